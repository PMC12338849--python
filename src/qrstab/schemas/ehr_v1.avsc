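{
  "type": "record",
  "name": "EHRRecord",
  "doc": "Deidentified structured health record: seven sections covering demographics, surgery, imaging, laboratory tests, risk assessments, diseases and discharge medication. Free-text fields carry logicalType 'tokenized-text' (replaced by packed 2-byte token ids when a tokenizer is supplied); dates carry 'epoch-days' (stored as day offsets from the schema's tag epoch).",
  "fields": [
    {"name": "base", "type": {"type": "record", "name": "Base", "fields": [
      {"name": "age", "type": "int"},
      {"name": "gender", "type": "string"},
      {"name": "height", "type": "double"},
      {"name": "weight", "type": "double"},
      {"name": "department", "type": {"type": "string", "logicalType": "tokenized-text"}},
      {"name": "hospitalDays", "type": "int"},
      {"name": "admissionDate", "type": {"type": "int", "logicalType": "epoch-days"}},
      {"name": "dischargeDate", "type": {"type": "int", "logicalType": "epoch-days"}},
      {"name": "nursingLevel", "type": {"type": "string", "logicalType": "tokenized-text"}},
      {"name": "allergyHistory", "type": ["null", {"type": "string", "logicalType": "tokenized-text"}]}
    ]}},
    {"name": "operate", "type": {"type": "array", "items": {"type": "record", "name": "Operation", "fields": [
      {"name": "surgeryName", "type": {"type": "string", "logicalType": "tokenized-text"}},
      {"name": "surgeryDate", "type": {"type": "int", "logicalType": "epoch-days"}}
    ]}}},
    {"name": "image", "type": {"type": "array", "items": {"type": "record", "name": "ImagingExam", "fields": [
      {"name": "examDate", "type": {"type": "int", "logicalType": "epoch-days"}},
      {"name": "examName", "type": {"type": "string", "logicalType": "tokenized-text"}},
      {"name": "bodyPart", "type": {"type": "string", "logicalType": "tokenized-text"}},
      {"name": "conclusion", "type": {"type": "string", "logicalType": "tokenized-text"}}
    ]}}},
    {"name": "lab", "type": {"type": "array", "items": {"type": "record", "name": "LabResult", "fields": [
      {"name": "indicatorName", "type": {"type": "string", "logicalType": "tokenized-text"}},
      {"name": "value", "type": "string"},
      {"name": "unit", "type": {"type": "string", "logicalType": "tokenized-text"}},
      {"name": "riskFlag", "type": "string"},
      {"name": "normalRange", "type": {"type": "string", "logicalType": "tokenized-text"}}
    ]}}},
    {"name": "ass", "type": {"type": "array", "items": {"type": "record", "name": "RiskAssessment", "fields": [
      {"name": "scaleName", "type": {"type": "string", "logicalType": "tokenized-text"}},
      {"name": "riskLevel", "type": "string"},
      {"name": "riskFactors", "type": {"type": "string", "logicalType": "tokenized-text"}}
    ]}}},
    {"name": "disease", "type": {"type": "array", "items": {"type": "record", "name": "Disease", "fields": [
      {"name": "diseaseName", "type": {"type": "string", "logicalType": "tokenized-text"}},
      {"name": "category", "type": {"type": "string", "logicalType": "tokenized-text"}}
    ]}}},
    {"name": "drug", "type": {"type": "array", "items": {"type": "record", "name": "Drug", "fields": [
      {"name": "drugName", "type": {"type": "string", "logicalType": "tokenized-text"}},
      {"name": "dailyDose", "type": "string"},
      {"name": "frequency", "type": {"type": "string", "logicalType": "tokenized-text"}}
    ]}}}
  ]
}
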