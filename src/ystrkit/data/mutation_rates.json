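{
  "version": "consensus-2010",
  "description": "Locus-specific Y-STR mutation rates per father-to-son transmission (published consensus estimates from large pedigree studies; rapidly mutating loci carry rates an order of magnitude above the standard set). Multi-copy loci carry the per-copy rate.",
  "rates": {
    "DYS19": 0.0023,
    "DYS389I": 0.0028,
    "DYS389II": 0.0036,
    "DYS390": 0.0021,
    "DYS391": 0.0026,
    "DYS392": 0.0005,
    "DYS393": 0.0012,
    "DYS437": 0.0012,
    "DYS438": 0.0004,
    "DYS439": 0.0050,
    "DYS448": 0.0014,
    "DYS456": 0.0042,
    "DYS458": 0.0064,
    "DYS635": 0.0038,
    "YGATAH4": 0.0024,
    "DYS449": 0.0122,
    "DYS460": 0.0057,
    "DYS481": 0.0050,
    "DYS518": 0.0184,
    "DYS533": 0.0037,
    "DYS570": 0.0124,
    "DYS576": 0.0143,
    "DYS627": 0.0123,
    "DYS385a": 0.0023,
    "DYS385b": 0.0023,
    "DYF387S1a": 0.0159,
    "DYF387S1b": 0.0159
  }
}
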