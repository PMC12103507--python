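column	term
SampleType	biological
SampleType	blank_extraction
SampleType	blank_QC
SampleType	blank_analysis
SampleType	culture
SampleType	food
SampleType	environmental
SampleType	reference material
BiologicalSex	male
BiologicalSex	female
BiologicalSex	intersex
BiologicalSex	not specified
LifeStage	infant
LifeStage	juvenile
LifeStage	adult
LifeStage	not specified
HealthStatus	healthy
HealthStatus	diseased
HealthStatus	not specified
IonizationSourceAndPolarity	electrospray ionization (positive)
IonizationSourceAndPolarity	electrospray ionization (negative)
IonizationSourceAndPolarity	electrospray ionization (alternating)
IonizationSourceAndPolarity	electrospray ionization
IonizationSourceAndPolarity	atmospheric pressure chemical ionization (positive)
IonizationSourceAndPolarity	atmospheric pressure chemical ionization (negative)
IonizationSourceAndPolarity	atmospheric pressure chemical ionization
ChromatographyAndPhase	reverse phase (C18)
ChromatographyAndPhase	reverse phase (C8)
ChromatographyAndPhase	normal phase (HILIC)
ChromatographyAndPhase	gas chromatography (other)
HumanPopulationDensity	urban
HumanPopulationDensity	rural
HumanPopulationDensity	not specified
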