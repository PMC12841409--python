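region	role	gene_id	start	end	strand	exons	colocated_with	ancestral_edge	category
BRI	boundary							1	fixed
BRII	boundary							2	fixed
BRIII	boundary							4	fixed
BRIV	boundary							6	fixed
X2 distal	distal	AATE009941	13261242	13265420	+	2-3		5	polymorphic
X2 distal	proximal	AATE005475	13236449	13246292	-	3		5	polymorphic
X2 proximal	distal	AATE016042	1465925	1468608	-	2-3	BRIV		polymorphic
X2 proximal	proximal	AATE009858	14520988	14521746	+	1	BRIV		polymorphic
X0 distal	distal	AATE021012	4398009	4404032	-	4		3	polymorphic
X0 distal	proximal	AATE013154	4571860	4577721	-	3		3	polymorphic
X0 proximal	distal	AATE003340	17252047	17256383	+	2		7	polymorphic
X0 proximal	proximal	AATE018776	17260494	17265377	-	2-4		7	polymorphic
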