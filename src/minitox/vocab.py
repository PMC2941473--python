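"""Fixed RDF vocabulary used across all resource serializations."""

RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS = "http://www.w3.org/2000/01/rdf-schema#"
XSD = "http://www.w3.org/2001/XMLSchema#"
DC = "http://purl.org/dc/elements/1.1/"
OT = "http://minitox.example/ot#"    # core terms
OTA = "http://minitox.example/ota#"  # algorithm-type classes
OTE = "http://minitox.example/ote#"  # endpoint classes

PREFIXES = {"rdf": RDF, "rdfs": RDFS, "xsd": XSD, "dc": DC, "ot": OT, "ota": OTA, "ote": OTE}

RDF_TYPE = RDF + "type"
RDFS_SUBCLASS = RDFS + "subClassOf"
RDFS_LABEL = RDFS + "label"
DC_TITLE = DC + "title"
DC_CREATOR = DC + "creator"
DC_DATE = DC + "date"

# core resource classes (mirrors the framework component model)
OT_DATASET = OT + "Dataset"
OT_DATAENTRY = OT + "DataEntry"
OT_COMPOUND = OT + "Compound"
OT_FEATURE = OT + "Feature"
OT_FEATURE_VALUE = OT + "FeatureValue"
OT_MODEL = OT + "Model"
OT_ALGORITHM = OT + "Algorithm"
OT_VALIDATION = OT + "Validation"
OT_AD_MODEL = OT + "ApplicabilityDomain"
OT_TASK = OT + "Task"

# core properties
OT_HAS_SOURCE = OT + "hasSource"
OT_SMILES = OT + "smiles"
OT_INCHI = OT + "inchi"
OT_NAME = OT + "name"
OT_ORIGIN = OT + "originInventory"
OT_INDEX = OT + "index"
OT_FEATURE_P = OT + "feature"
OT_COMPOUND_P = OT + "compound"
OT_ENTRY_P = OT + "dataEntry"
OT_VALUE_P = OT + "value"
OT_VALUES_P = OT + "values"
OT_VALUE_KIND = OT + "valueKind"
OT_ACCEPT_VALUE = OT + "acceptValue"
OT_ENDPOINT_REF = OT + "endpoint"
OT_UNITS = OT + "units"
OT_ALGORITHM_P = OT + "algorithm"
OT_PARAMETERS = OT + "parameters"
OT_TRAINING_DATASET = OT + "trainingDataset"
OT_INDEP = OT + "independentVariables"
OT_DEP = OT + "dependentVariables"
OT_PREDICTED = OT + "predictedVariables"
OT_CONFIDENCE = OT + "confidenceFeature"
OT_STATE = OT + "trainedState"
OT_METHOD = OT + "method"
OT_THRESHOLD = OT + "threshold"
OT_BOUNDS = OT + "bounds"
OT_REFERENCE = OT + "reference"
OT_SPLIT_PLAN = OT + "splitPlan"
OT_FOLD_METRICS = OT + "foldMetrics"
OT_AGG_METRICS = OT + "aggregateMetrics"
OT_FOLD_INFO = OT + "foldInfo"
OT_MODEL_URIS = OT + "modelUris"
OT_DATASET_HASH = OT + "datasetHash"
OT_SNAPSHOT = OT + "snapshotHash"

# algorithm-type ontology classes
OTA_CLASSES = {
    "DescriptorCalculation": OTA + "DescriptorCalculation",
    "Classification": OTA + "Classification",
    "Regression": OTA + "Regression",
    "FeatureSelection": OTA + "FeatureSelection",
    "DataCleanup": OTA + "DataCleanup",
}
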