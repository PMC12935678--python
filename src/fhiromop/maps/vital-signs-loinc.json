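{
  "resourceType": "ConceptMap",
  "id": "vital-signs-loinc",
  "status": "active",
  "title": "Vital-sign LOINC codes to OHDSI concept ids",
  "group": [
    {
      "source": "http://loinc.org",
      "target": "https://athena.ohdsi.org",
      "element": [
        {
          "code": "8310-5",
          "display": "Body temperature",
          "target": [
            {
              "code": "3020891",
              "display": "Body temperature",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "9279-1",
          "display": "Respiratory rate",
          "target": [
            {
              "code": "3024171",
              "display": "Respiratory rate",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "8867-4",
          "display": "Heart rate",
          "target": [
            {
              "code": "3027018",
              "display": "Heart rate",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "2708-6",
          "display": "Oxygen saturation in Arterial blood",
          "target": [
            {
              "code": "3016502",
              "display": "Oxygen saturation in Arterial blood",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "29463-7",
          "display": "Body weight",
          "target": [
            {
              "code": "3025315",
              "display": "Body weight",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "8302-2",
          "display": "Body height",
          "target": [
            {
              "code": "3036277",
              "display": "Body height",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "9843-4",
          "display": "Head Occipital-frontal circumference",
          "target": [
            {
              "code": "3001537",
              "display": "Head Occipital-frontal circumference",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "39156-5",
          "display": "Body mass index (BMI) [Ratio]",
          "target": [
            {
              "code": "3038553",
              "display": "Body mass index (BMI) [Ratio]",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "85354-9",
          "display": "Blood pressure panel with all children optional",
          "target": [
            {
              "code": "36310251",
              "display": "Systolic and diastolic blood pressure",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "8480-6",
          "display": "Systolic blood pressure",
          "target": [
            {
              "code": "3004249",
              "display": "Systolic blood pressure",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "8462-4",
          "display": "Diastolic blood pressure",
          "target": [
            {
              "code": "3012888",
              "display": "Diastolic blood pressure",
              "relationship": "equivalent"
            }
          ]
        }
      ]
    },
    {
      "source": "https://athena.ohdsi.org",
      "target": "http://loinc.org",
      "element": [
        {
          "code": "3020891",
          "display": "Body temperature",
          "target": [
            {
              "code": "8310-5",
              "display": "Body temperature",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "3024171",
          "display": "Respiratory rate",
          "target": [
            {
              "code": "9279-1",
              "display": "Respiratory rate",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "3027018",
          "display": "Heart rate",
          "target": [
            {
              "code": "8867-4",
              "display": "Heart rate",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "3016502",
          "display": "Oxygen saturation in Arterial blood",
          "target": [
            {
              "code": "2708-6",
              "display": "Oxygen saturation in Arterial blood",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "3025315",
          "display": "Body weight",
          "target": [
            {
              "code": "29463-7",
              "display": "Body weight",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "3036277",
          "display": "Body height",
          "target": [
            {
              "code": "8302-2",
              "display": "Body height",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "3001537",
          "display": "Head Occipital-frontal circumference",
          "target": [
            {
              "code": "9843-4",
              "display": "Head Occipital-frontal circumference",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "3038553",
          "display": "Body mass index (BMI) [Ratio]",
          "target": [
            {
              "code": "39156-5",
              "display": "Body mass index (BMI) [Ratio]",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "36310251",
          "display": "Systolic and diastolic blood pressure",
          "target": [
            {
              "code": "85354-9",
              "display": "Blood pressure panel with all children optional",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "3004249",
          "display": "Systolic blood pressure",
          "target": [
            {
              "code": "8480-6",
              "display": "Systolic blood pressure",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "3012888",
          "display": "Diastolic blood pressure",
          "target": [
            {
              "code": "8462-4",
              "display": "Diastolic blood pressure",
              "relationship": "equivalent"
            }
          ]
        }
      ]
    }
  ]
}
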