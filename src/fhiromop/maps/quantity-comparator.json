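{
  "resourceType": "ConceptMap",
  "id": "quantity-comparator",
  "status": "active",
  "title": "FHIR quantity comparators to OHDSI operator concept ids",
  "group": [
    {
      "source": "http://hl7.org/fhir/quantity-comparator",
      "target": "https://athena.ohdsi.org",
      "element": [
        {
          "code": "<",
          "display": "Less than",
          "target": [
            {
              "code": "4171756",
              "display": "<",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "<=",
          "display": "Less than or equal to",
          "target": [
            {
              "code": "4171754",
              "display": "<=",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": ">=",
          "display": "Greater than or equal to",
          "target": [
            {
              "code": "4171755",
              "display": ">=",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": ">",
          "display": "Greater than",
          "target": [
            {
              "code": "4172704",
              "display": ">",
              "relationship": "equivalent"
            }
          ]
        }
      ]
    },
    {
      "source": "https://athena.ohdsi.org",
      "target": "http://hl7.org/fhir/quantity-comparator",
      "element": [
        {
          "code": "4171756",
          "display": "<",
          "target": [
            {
              "code": "<",
              "display": "Less than",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "4171754",
          "display": "<=",
          "target": [
            {
              "code": "<=",
              "display": "Less than or equal to",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "4171755",
          "display": ">=",
          "target": [
            {
              "code": ">=",
              "display": "Greater than or equal to",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "4172704",
          "display": ">",
          "target": [
            {
              "code": ">",
              "display": "Greater than",
              "relationship": "equivalent"
            }
          ]
        }
      ]
    }
  ]
}
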