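source_pattern	match_mode	target_term	target_column
solvent blank	exact	blank_extraction	SampleType
extraction blank	exact	blank_extraction	SampleType
process blank	exact	blank_extraction	SampleType
qc	exact	blank_QC	SampleType
pooled qc	exact	blank_QC	SampleType
pool	exact	blank_QC	SampleType
biological	exact	biological	SampleType
blank	substring	blank_analysis	SampleType
quality control	substring	blank_QC	SampleType
plasma	substring	blood plasma	UBERONBodyPartName
serum	substring	blood serum	UBERONBodyPartName
urine	substring	urine	UBERONBodyPartName
stool	substring	feces	UBERONBodyPartName
fecal	substring	feces	UBERONBodyPartName
ventricular	substring	heart	UBERONBodyPartName
myocardium	substring	myocardium	UBERONBodyPartName
female	exact	female	BiologicalSex
f	exact	female	BiologicalSex
woman	exact	female	BiologicalSex
male	exact	male	BiologicalSex
m	exact	male	BiologicalSex
man	exact	male	BiologicalSex
not specified	exact	not specified	BiologicalSex
healthy	exact	healthy	HealthStatus
control	exact	healthy	HealthStatus
diseased	exact	diseased	HealthStatus
patient	exact	diseased	HealthStatus
reversed phase	substring	reverse phase (C18)	ChromatographyAndPhase
reverse phase	substring	reverse phase (C18)	ChromatographyAndPhase
c18	substring	reverse phase (C18)	ChromatographyAndPhase
hilic	substring	normal phase (HILIC)	ChromatographyAndPhase
gas chromatography	substring	gas chromatography (other)	ChromatographyAndPhase
esi positive	exact	electrospray ionization (positive)	IonizationSourceAndPolarity
esi negative	exact	electrospray ionization (negative)	IonizationSourceAndPolarity
electrospray	substring	electrospray ionization	IonizationSourceAndPolarity
apci	substring	atmospheric pressure chemical ionization	IonizationSourceAndPolarity
urban	exact	urban	HumanPopulationDensity
rural	exact	rural	HumanPopulationDensity
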