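{
  "resourceType": "ConceptMap",
  "id": "ucum-units",
  "status": "active",
  "title": "UCUM unit codes to OHDSI unit concept ids",
  "group": [
    {
      "source": "http://unitsofmeasure.org",
      "target": "https://athena.ohdsi.org",
      "element": [
        {
          "code": "Cel",
          "display": "degree Celsius",
          "target": [
            {
              "code": "586323",
              "display": "degree Celsius",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "/min",
          "display": "per minute",
          "target": [
            {
              "code": "8541",
              "display": "per minute",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "%",
          "display": "percent",
          "target": [
            {
              "code": "8554",
              "display": "percent",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "kg",
          "display": "kilogram",
          "target": [
            {
              "code": "9529",
              "display": "kilogram",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "cm",
          "display": "centimeter",
          "target": [
            {
              "code": "8582",
              "display": "centimeter",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "kg/m2",
          "display": "kilogram per square meter",
          "target": [
            {
              "code": "9531",
              "display": "kilogram per square meter",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "mm[Hg]",
          "display": "millimeter of mercury",
          "target": [
            {
              "code": "8876",
              "display": "millimeter mercury column",
              "relationship": "equivalent"
            }
          ]
        }
      ]
    },
    {
      "source": "https://athena.ohdsi.org",
      "target": "http://unitsofmeasure.org",
      "element": [
        {
          "code": "586323",
          "display": "degree Celsius",
          "target": [
            {
              "code": "Cel",
              "display": "degree Celsius",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "8541",
          "display": "per minute",
          "target": [
            {
              "code": "/min",
              "display": "per minute",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "8554",
          "display": "percent",
          "target": [
            {
              "code": "%",
              "display": "percent",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "9529",
          "display": "kilogram",
          "target": [
            {
              "code": "kg",
              "display": "kilogram",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "8582",
          "display": "centimeter",
          "target": [
            {
              "code": "cm",
              "display": "centimeter",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "9531",
          "display": "kilogram per square meter",
          "target": [
            {
              "code": "kg/m2",
              "display": "kilogram per square meter",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "8876",
          "display": "millimeter mercury column",
          "target": [
            {
              "code": "mm[Hg]",
              "display": "millimeter of mercury",
              "relationship": "equivalent"
            }
          ]
        }
      ]
    }
  ]
}
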