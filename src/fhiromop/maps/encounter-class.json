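{
  "resourceType": "ConceptMap",
  "id": "encounter-class",
  "status": "active",
  "title": "v3 ActCode encounter class to OHDSI visit concept ids",
  "group": [
    {
      "source": "http://terminology.hl7.org/CodeSystem/v3-ActCode",
      "target": "https://athena.ohdsi.org",
      "element": [
        {
          "code": "AMB",
          "display": "ambulatory",
          "target": [
            {
              "code": "9202",
              "display": "Outpatient Visit",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "IMP",
          "display": "inpatient encounter",
          "target": [
            {
              "code": "9201",
              "display": "Inpatient Visit",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "EMER",
          "display": "emergency",
          "target": [
            {
              "code": "9203",
              "display": "Emergency Room Visit",
              "relationship": "equivalent"
            }
          ]
        }
      ]
    }
  ]
}
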