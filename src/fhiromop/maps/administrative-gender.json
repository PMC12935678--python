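{
  "resourceType": "ConceptMap",
  "id": "administrative-gender",
  "status": "active",
  "title": "FHIR administrative gender to OHDSI gender concept ids",
  "group": [
    {
      "source": "http://hl7.org/fhir/administrative-gender",
      "target": "https://athena.ohdsi.org",
      "element": [
        {
          "code": "male",
          "display": "Male",
          "target": [
            {
              "code": "8507",
              "display": "MALE",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "female",
          "display": "Female",
          "target": [
            {
              "code": "8532",
              "display": "FEMALE",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "other",
          "display": "Other",
          "target": [
            {
              "code": "8521",
              "display": "OTHER",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "unknown",
          "display": "Unknown",
          "target": [
            {
              "code": "8551",
              "display": "UNKNOWN",
              "relationship": "equivalent"
            }
          ]
        }
      ]
    }
  ]
}
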