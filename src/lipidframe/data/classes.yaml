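# Default lipid class templates for direct-infusion brain lipidomics.
#
# backbone: molecular formula of the headgroup-bearing core before chain
#   esterification (glycerophosphocholine for PC, glycerol for TAG, ...).
#   For sphingoid classes it is the headgroup added to the ceramide core.
# n_ether: number of ester bonds replaced by ether linkages (-O +H2 each).
# Ranges are inclusive [low, high] on C index, db index and OH index.
classes:
  "LPC":
    category: glycerophospholipid
    backbone: C8H20NO6P
    n_chains: 1
    adducts: ["+H"]
    c_range: [14, 24]
    db_range: [0, 6]
  "LPC O-":
    category: glycerophospholipid
    backbone: C8H20NO6P
    n_chains: 1
    n_ether: 1
    adducts: ["+H"]
    c_range: [14, 24]
    db_range: [0, 6]
  "LPE":
    category: glycerophospholipid
    backbone: C5H14NO6P
    n_chains: 1
    adducts: ["+H"]
    c_range: [14, 24]
    db_range: [0, 6]
  "PC":
    category: glycerophospholipid
    backbone: C8H20NO6P
    n_chains: 2
    adducts: ["+H"]
    c_range: [28, 44]
    db_range: [0, 10]
  "PC O-":
    category: glycerophospholipid
    backbone: C8H20NO6P
    n_chains: 2
    n_ether: 1
    adducts: ["+H"]
    c_range: [28, 44]
    db_range: [0, 10]
  "PE":
    category: glycerophospholipid
    backbone: C5H14NO6P
    n_chains: 2
    adducts: ["+H"]
    c_range: [28, 44]
    db_range: [0, 10]
  "PE O-":
    category: glycerophospholipid
    backbone: C5H14NO6P
    n_chains: 2
    n_ether: 1
    adducts: ["+H"]
    c_range: [28, 44]
    db_range: [0, 10]
  "LPA":
    category: glycerophospholipid
    backbone: C3H9O6P
    n_chains: 1
    adducts: ["-H"]
    c_range: [14, 24]
    db_range: [0, 6]
  "LPA O-":
    category: glycerophospholipid
    backbone: C3H9O6P
    n_chains: 1
    n_ether: 1
    adducts: ["-H"]
    c_range: [14, 24]
    db_range: [0, 6]
  "LPS":
    category: glycerophospholipid
    backbone: C6H14NO8P
    n_chains: 1
    adducts: ["-H"]
    c_range: [14, 24]
    db_range: [0, 6]
  "LPI":
    category: glycerophospholipid
    backbone: C9H19O11P
    n_chains: 1
    adducts: ["-H"]
    c_range: [14, 24]
    db_range: [0, 6]
  "PA":
    category: glycerophospholipid
    backbone: C3H9O6P
    n_chains: 2
    adducts: ["-H"]
    c_range: [28, 44]
    db_range: [0, 10]
  "PS":
    category: glycerophospholipid
    backbone: C6H14NO8P
    n_chains: 2
    adducts: ["-H"]
    c_range: [28, 44]
    db_range: [0, 10]
  "PI":
    category: glycerophospholipid
    backbone: C9H19O11P
    n_chains: 2
    adducts: ["-H"]
    c_range: [28, 44]
    db_range: [0, 10]
  "PG":
    category: glycerophospholipid
    backbone: C6H15O8P
    n_chains: 2
    adducts: ["-H"]
    c_range: [28, 44]
    db_range: [0, 10]
  "DAG":
    category: glycerolipid
    backbone: C3H8O3
    n_chains: 2
    adducts: ["+NH4"]
    c_range: [28, 44]
    db_range: [0, 10]
  "TAG":
    category: glycerolipid
    backbone: C3H8O3
    n_chains: 3
    adducts: ["+NH4"]
    c_range: [40, 60]
    db_range: [0, 12]
  "CE":
    category: sterol lipid
    backbone: C27H46O
    n_chains: 1
    adducts: ["+NH4"]
    c_range: [12, 22]
    db_range: [0, 6]
  "Cer":
    category: sphingolipid
    backbone: ""
    n_chains: 2
    chain_model: sphingoid
    adducts: ["+H"]
    c_range: [30, 44]
    db_range: [0, 3]
    oh_range: [1, 3]
  "SM":
    category: sphingolipid
    backbone: C5H12NO3P
    n_chains: 2
    chain_model: sphingoid
    adducts: ["+H"]
    c_range: [30, 44]
    db_range: [0, 3]
    oh_range: [1, 3]
  "HexCer":
    category: sphingolipid
    backbone: C6H10O5
    n_chains: 2
    chain_model: sphingoid
    adducts: ["+H"]
    c_range: [28, 44]
    db_range: [0, 3]
    oh_range: [2, 3]
  "SHexCer":
    category: sphingolipid
    backbone: C6H10O8S
    n_chains: 2
    chain_model: sphingoid
    adducts: ["-H"]
    c_range: [28, 44]
    db_range: [0, 3]
    oh_range: [2, 3]

# Internal standards: free-text display label -> sum-composition species name.
internal_standards:
  "CE 19:0 (IS)": "CE 19:0"
  "TAG 17:1/17:1/17:1": "TAG 51:3"
  "DAG 19:0/19:0": "DAG 38:0"
  "LPA O-16:0": "LPA O-16:0"
  "PA 17:0/14:1": "PA 31:1"
  "LPS 17:1 (IS)": "LPS 17:1"
  "PS 17:0/20:4": "PS 37:4"
  "PE O-20:0/O-20:0": "PE O-40:0"
  "LPC O-17:0": "LPC O-17:0"
  "PC 18:3/18:3": "PC 36:6"
  "PI 17:0/20:4": "PI 37:4"
  "PG 17:0/17:0": "PG 34:0"
  "Cer 18:1;2/17:0;0": "Cer 35:1;2"
  "SM 18:1;2/17:0;0": "SM 35:1;2"
  "HexCer 18:1;2/12:0;0": "HexCer 30:1;2"
  "SHexCer 18:1;2/12:0;0": "SHexCer 30:1;2"
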