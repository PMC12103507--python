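column	kind	description
MRI	key	MS Run Identifier, the unique key (mzspec:accession:path)
SourceRepository	repository	Repository hosting the run (GNPS/MassIVE, MTBLS, NMDR)
NCBITaxonomy	taxonomy	Analyzed organism as taxid|scientific name
SampleType	vocab	Broad sample class incl. blank/QC designations
UBERONBodyPartName	vocab	Body part, plant part, or cell type of the sample
BiologicalSex	vocab	Biological sex of the subject
AgeInYears	free	Subject age in years at collection
LifeStage	vocab	Developmental stage of the subject
DOIDCommonName	vocab	Disease diagnosis (human-readable DOID term)
HealthStatus	vocab	Coarse healthy/diseased status
MassSpectrometer	vocab	Instrument model used for acquisition
IonizationSourceAndPolarity	vocab	Ion source with acquisition polarity
ChromatographyAndPhase	vocab	Separation technique and stationary phase
YearOfAnalysis	year	Four-digit year the data were acquired
Country	free	Country of sample collection
HumanPopulationDensity	vocab	Urban/rural classification of the collection site
LatitudeandLongitude	coordinate	Collection coordinates as lat|lon decimal degrees
SampleCollectionMethod	free	How the sample was collected
SubjectIdentifierAsRecorded	free	Submitter-recorded subject identifier
UniqueSubjectID	free	Stable subject identifier across datasets
DepthorAltitudeMeters	free	Collection depth or altitude in meters
ProvenanceIdentifiers	free	Source study/analysis identifiers the record was harmonized from
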