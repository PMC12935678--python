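{
  "resourceType": "ConceptMap",
  "id": "place-of-service",
  "status": "active",
  "title": "Organization type / admit source / discharge disposition to OHDSI place-of-service concept ids",
  "group": [
    {
      "source": "http://terminology.hl7.org/CodeSystem/organization-type",
      "target": "https://athena.ohdsi.org",
      "element": [
        {
          "code": "prov",
          "display": "Healthcare Provider",
          "target": [
            {
              "code": "8940",
              "display": "Office",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "dept",
          "display": "Hospital Department",
          "target": [
            {
              "code": "8756",
              "display": "Outpatient Hospital",
              "relationship": "equivalent"
            }
          ]
        }
      ]
    },
    {
      "source": "http://terminology.hl7.org/CodeSystem/admit-source",
      "target": "https://athena.ohdsi.org",
      "element": [
        {
          "code": "gp",
          "display": "General Practitioner referral",
          "target": [
            {
              "code": "8940",
              "display": "Office",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "emd",
          "display": "From accident/emergency department",
          "target": [
            {
              "code": "8870",
              "display": "Emergency Room - Hospital",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "hosp-trans",
          "display": "Transferred from other hospital",
          "target": [
            {
              "code": "8717",
              "display": "Inpatient Hospital",
              "relationship": "equivalent"
            }
          ]
        }
      ]
    },
    {
      "source": "http://terminology.hl7.org/CodeSystem/discharge-disposition",
      "target": "https://athena.ohdsi.org",
      "element": [
        {
          "code": "home",
          "display": "Home",
          "target": [
            {
              "code": "8536",
              "display": "Home",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "snf",
          "display": "Skilled nursing facility",
          "target": [
            {
              "code": "8863",
              "display": "Skilled Nursing Facility",
              "relationship": "equivalent"
            }
          ]
        },
        {
          "code": "other-hcf",
          "display": "Other healthcare facility",
          "target": [
            {
              "code": "8717",
              "display": "Inpatient Hospital",
              "relationship": "equivalent"
            }
          ]
        }
      ]
    }
  ]
}
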