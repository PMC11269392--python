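case_id	age_years	sex	location	reference_diagnosis	lesion_type	pretreatment	microarray_mc	nanopore_mc	score_mc	nanopore_mcf	score_mcf	tsne_concordant	concordant
DX-BLN-025	8	F	Parieto-occipital right	CNS neuroblastoma	primary	None	CNS neuroblastoma with FOXR2 activation	CNS neuroblastoma with FOXR2 activation	0.68	CNS neuroblastoma with FOXR2 activation	0.68	+	true
DX-BLN-027	17	F	Right trigeminal nerve	Schwannoma	primary	None	schwannoma	schwannoma	0.85	schwannoma	0.85	+	true
DX-BLN-028	9	F	Right cerebellar hemisphere	Pilocytic astrocytoma	primary	None	low grade glioma, subclass posterior fossa pilocytic astrocytoma	low grade glioma, subclass posterior fossa pilocytic astrocytoma	0.44	pilocytic astrocytoma	0.58	+	true
DX-BLN-029	1	F	Fronto-temporo-parietal right	Ependymoma	secondary	Cyclophosphamide/vincristine/methotrexate/carboplatin/etoposide	ependymoma, YAP fusion	ependymoma, YAP fusion	0.07	glioblastoma, IDH wildtype	0.10	+	true
DX-BLN-037	5	F	Right cerebellar hemisphere	Pilocytic astrocytoma	secondary	Vincristine/carboplatin	low grade glioma, subclass posterior fossa pilocytic astrocytoma	low grade glioma, subclass posterior fossa pilocytic astrocytoma	0.33	pilocytic astrocytoma	0.54	+	true
DX-BLN-042	9	F	Left cerebellar hemisphere	Pilocytic astrocytoma	primary	None	low grade glioma, subclass posterior fossa pilocytic astrocytoma	low grade glioma, subclass posterior fossa pilocytic astrocytoma	0.46	pilocytic astrocytoma	0.56	+	true
DX-BLN-043	10	M	Left frontal	Ependymoma, RELA fusion-positive	primary	None	ependymoma, RELA fusion	ependymoma, RELA fusion	0.43	ependymoma, RELA fusion	0.43	+	true
DX-BLN-044	9	F	Left temporo-parieto-thalamic	High grade glioma, H3 K27M mutated	secondary	None	Diffuse midline glioma, K27-mutant	Diffuse midline glioma, K27-mutant	0.66	Diffuse midline glioma, K27-mutant	0.66	+	true
DX-BLN-047	8	F	Left mesencephalic	Pilocytic astrocytoma	secondary	Vincristine/carboplatin	low grade glioma, subclass posterior fossa pilocytic astrocytoma	low grade glioma, subclass posterior fossa pilocytic astrocytoma	0.34	pilocytic astrocytoma	0.50	+	true
DX-BLN-048	3	M	IV. Ventricle	Anaplastic Ependymoma	primary	None	ependymoma, posterior fossa group A	ependymoma, posterior fossa group A	0.75	ependymoma, posterior fossa group A	0.75	+	true
DX-BLN-049	3	F	Thoracic spine	Pilocytic astrocytoma	primary	None	low grade glioma, subclass posterior fossa pilocytic astrocytoma	low grade glioma, subclass midline pilocytic astrocytoma	0.07	pilocytic astrocytoma	0.12	-	false
DX-BLN-050	15	F	Right lateral ventricle	Atypical central neurocytoma	primary	None	central neurocytoma	central neurocytoma	0.72	central neurocytoma	0.72	+	true
DX-BLN-054	16	F	Left frontal	Diffuse astrocytoma, IDH-mutant	primary	None	IDH glioma, subclass astrocytoma	control tissue, hemispheric cortex	0.08	pilocytic astrocytoma	0.17	-	false
DX-BLN-064	6	F	Foramen Monroi right	Subependymal giant cell astrocytoma	primary	None	N/A	low grade glioma, subependymal giant cell astrocytoma	0.15	low grade glioma, subependymal giant cell astrocytoma	0.15	-	true
DX-BLN-065	6	M	Right mesencephalic	Pilocytic astrocytoma	secondary	Vincristine/carboplatin	low grade glioma, subclass posterior fossa pilocytic astrocytoma	low grade glioma, subclass posterior fossa pilocytic astrocytoma	0.24	pilocytic astrocytoma	0.47	+	true
DX-BLN-071	7	F	Optic pathway	Pilocytic astrocytoma	secondary	Vincristine/carboplatin, vinblastine, MEK inhibitor	N/A	low grade glioma, subclass midline pilocytic astrocytoma	0.37	pilocytic astrocytoma	0.48	+	true
DX-BLN-073	7	M	Sella turcica	Craniopharyngioma	primary	None	craniopharyngioma, adamantinomatous	craniopharyngioma, adamantinomatous	0.56	craniopharyngioma, adamantinomatous	0.56	+	true
DX-BLN-074	6	M	Right cerebellar hemisphere	Pilocytic astrocytoma	primary	None	low grade glioma, subclass posterior fossa pilocytic astrocytoma	low grade glioma, subclass posterior fossa pilocytic astrocytoma	0.58	pilocytic astrocytoma	0.69	+	true
DX-BLN-075	9	M	Right cerebellar hemisphere	Pilocytic astrocytoma	secondary	None	low grade glioma, subclass posterior fossa pilocytic astrocytoma	low grade glioma, subclass posterior fossa pilocytic astrocytoma	0.32	pilocytic astrocytoma	0.40	+	true
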