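[
  {
    "record_id": "rabbit_28S",
    "molecule_class": "28S",
    "species": "Oryctolagus cuniculus",
    "accessions": ["URS00009AB771_9986"],
    "is_template": true
  },
  {
    "record_id": "rabbit_28S_genomic",
    "molecule_class": "28S",
    "species": "Oryctolagus cuniculus",
    "accessions": ["AAGW00000000.2", "GL019111", "RF02543"]
  },
  {
    "record_id": "rabbit_18S",
    "molecule_class": "18S",
    "species": "Oryctolagus cuniculus",
    "accessions": ["URS00006F07B6_9986"],
    "expected_length": 1869,
    "is_template": true
  },
  {
    "record_id": "rabbit_5.8S",
    "molecule_class": "5.8S",
    "species": "Oryctolagus cuniculus",
    "accessions": ["URS00006CE1FB_9986"],
    "is_template": true
  },
  {
    "record_id": "rabbit_5S",
    "molecule_class": "5S",
    "species": "Oryctolagus cuniculus",
    "accessions": ["URS00006C8ED4_9986"],
    "expected_length": 144,
    "is_template": true
  },
  {
    "record_id": "human_18S",
    "molecule_class": "18S",
    "species": "Homo sapiens",
    "accessions": ["NR_145820.1"],
    "expected_length": 1869
  },
  {
    "record_id": "rabbit_18S_1982",
    "molecule_class": "18S",
    "species": "Oryctolagus cuniculus (1982 RefSeq)",
    "accessions": ["NR_033238.1"],
    "expected_length": 1863
  },
  {
    "record_id": "rabbit_18S_shotgun_locus",
    "molecule_class": "18S",
    "species": "Oryctolagus cuniculus (OryCun2.0 locus)",
    "accessions": ["NW_003159740.1"],
    "expected_length": 1869
  },
  {
    "record_id": "yeast_18S",
    "molecule_class": "18S",
    "species": "Saccharomyces cerevisiae",
    "accessions": ["NG_063315.1"],
    "expected_length": 1730
  },
  {
    "record_id": "klactis_18S",
    "molecule_class": "18S",
    "species": "Kluyveromyces lactis",
    "accessions": ["NG_063256.1"],
    "expected_length": 1748
  },
  {
    "record_id": "boar_28S",
    "molecule_class": "28S",
    "species": "Sus scrofa",
    "accessions": ["URS0000C12F10_9823"]
  },
  {
    "record_id": "human_28S",
    "molecule_class": "28S",
    "species": "Homo sapiens",
    "accessions": ["URS00027DEF72_9606"]
  }
]
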