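{
  "comment": "Consensus anthropoid topology with node ages in My. Anchored ages: Catarrhini 30 (onset of the ape ancestral branch), Hominoidea 20 (onset of the great-ape ancestral branch), Hominidae 10 (onset of the Homo-Pan ancestral branch), HomoPan 6 (onset of the human terminal lineage), root 46 (span of divergent anthropoid evolution covered by the sample). Remaining ages are literature-standard consensus dates.",
  "name": "Anthropoidea",
  "age": 46.0,
  "children": [
    {
      "name": "Catarrhini",
      "age": 30.0,
      "children": [
        {
          "name": "Hominoidea",
          "age": 20.0,
          "children": [
            {"name": "Hylobates_lar"},
            {
              "name": "Hominidae",
              "age": 10.0,
              "children": [
                {"name": "Gorilla_gorilla"},
                {
                  "name": "HomoPan",
                  "age": 6.0,
                  "children": [
                    {"name": "Pan_troglodytes"},
                    {"name": "Homo_sapiens"}
                  ]
                }
              ]
            }
          ]
        },
        {
          "name": "Cercopithecoidea",
          "age": 18.0,
          "children": [
            {
              "name": "Cercopithecinae",
              "age": 11.5,
              "children": [
                {"name": "Papio_anubis"},
                {
                  "name": "Cercopithecini",
                  "age": 9.5,
                  "children": [
                    {"name": "Miopithecus_talapoin"},
                    {
                      "name": "CercopithecinCore",
                      "age": 8.5,
                      "children": [
                        {"name": "Erythrocebus_patas"},
                        {
                          "name": "Cercopithecus",
                          "age": 6.5,
                          "children": [
                            {"name": "Cercopithecus_mitis"},
                            {"name": "Cercopithecus_ascanius"}
                          ]
                        }
                      ]
                    }
                  ]
                }
              ]
            },
            {
              "name": "Colobinae",
              "age": 13.0,
              "children": [
                {"name": "Nasalis_larvatus"},
                {"name": "Procolobus_badius"}
              ]
            }
          ]
        }
      ]
    },
    {
      "name": "Platyrrhini",
      "age": 25.0,
      "children": [
        {"name": "Pithecia_monachus"},
        {
          "name": "CebidaeAtelidae",
          "age": 23.0,
          "children": [
            {
              "name": "Atelidae",
              "age": 19.0,
              "children": [
                {"name": "Alouatta_seniculus"},
                {
                  "name": "Atelinae",
                  "age": 13.0,
                  "children": [
                    {"name": "Ateles_geoffroyi"},
                    {"name": "Lagothrix_lagotricha"}
                  ]
                }
              ]
            },
            {"name": "Cebus_albifrons"}
          ]
        }
      ]
    }
  ]
}
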