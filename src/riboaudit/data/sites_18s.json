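[
  {
    "site_name": "A-site (G626)",
    "note": "A1825 contact",
    "scheme_id": "human_18S",
    "position": 626,
    "expected_base": "G"
  },
  {
    "site_name": "A-site (C1331)",
    "note": "tRNA base",
    "scheme_id": "human_18S",
    "position": 1331,
    "expected_base": "C"
  },
  {
    "site_name": "A-site (A1825)",
    "note": "mRNA contact",
    "scheme_id": "human_18S",
    "position": 1825,
    "expected_base": "A"
  },
  {
    "site_name": "P-site (U1248)",
    "note": "tRNA base",
    "scheme_id": "human_18S",
    "position": 1248,
    "expected_base": "U"
  },
  {
    "site_name": "P-site (C1701)",
    "note": "tRNA base",
    "scheme_id": "human_18S",
    "position": 1701,
    "expected_base": "C"
  },
  {
    "site_name": "G183",
    "note": "missing from the 1982 rabbit RefSeq",
    "scheme_id": "rabbit_18S",
    "position": 183,
    "expected_base": "G"
  },
  {
    "site_name": "C1513",
    "note": "missing from the 1982 rabbit RefSeq",
    "scheme_id": "rabbit_18S",
    "position": 1513,
    "expected_base": "C"
  },
  {
    "site_name": "h18 G613",
    "note": "helix 18 ordering diagnostic",
    "scheme_id": "rabbit_18S",
    "position": 613,
    "expected_base": "G"
  },
  {
    "site_name": "h18 C614",
    "note": "helix 18 ordering diagnostic",
    "scheme_id": "rabbit_18S",
    "position": 614,
    "expected_base": "C"
  },
  {
    "site_name": "ES7 U1115",
    "note": "HCV IRES contact; numbering scheme unverified",
    "scheme_id": "human_18S",
    "position": 1115,
    "expected_base": null,
    "scheme_verified": false
  },
  {
    "site_name": "ES7 C1116",
    "note": "HCV IRES contact; numbering scheme unverified",
    "scheme_id": "human_18S",
    "position": 1116,
    "expected_base": null,
    "scheme_verified": false
  },
  {
    "site_name": "28S A3760",
    "note": "IAPV IRES contact; numbering scheme unverified",
    "scheme_id": "rabbit_28S",
    "position": 3760,
    "expected_base": null,
    "scheme_verified": false
  },
  {
    "site_name": "28S A4255",
    "note": "IAPV IRES contact; numbering scheme unverified",
    "scheme_id": "rabbit_28S",
    "position": 4255,
    "expected_base": null,
    "scheme_verified": false
  }
]
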