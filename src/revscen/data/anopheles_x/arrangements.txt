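# Signed block arrangements of the X chromosome (8 syntenic blocks,
# distal/telomeric end first, block 8 carries the centromere).
# ancestral: gene order of the outgroup reference (An. atroparvus).
# X1: shared arrangement of An. messeae and An. daciae (two nested fixed
#     inversions relative to the ancestral order).
# X2: An. messeae polymorphic arrangement, one reversal from X1 (derived
#     from junction constraints, not printed as a signed order in the source
#     data).
# X0: An. daciae polymorphic arrangement, one reversal from X1 (derived the
#     same way).
>ancestral
1 2 3 4 5 6 7 8 $
>X1
1 -6 -5 3 4 -2 7 8 $
>X2
1 -6 2 -4 -3 5 7 8 $
>X0
1 -6 -5 3 -7 2 -4 8 $
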