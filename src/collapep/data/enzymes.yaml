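# Cleavage-specificity table for simulated proteolysis.
#
# Each enzyme maps to {ec, specs, exceptions}. A spec constrains a subset of
# the P2/P1/P1'/P2' positions around the scissile bond to a residue string;
# the enzyme cleaves a bond iff some spec matches and no exception matches.
#
# Sources: trypsin/chymotrypsin/elastase follow the classical serine-protease
# specificities as encoded by ExPASy PeptideCutter. The cysteine proteases
# (papain, ficin, stem bromelain, calpain 2) have broad, subsite-driven
# specificities whose database encodings are not published; the entries below
# are simplified encodings of their reported subsite preferences (papain:
# bulky hydrophobic at P2; ficin: papain-like with aromatic P1 preference;
# bromelain: basic/alanyl P1 with aliphatic P2; calpain 2: Leu/Val at P2 with
# Tyr/Met/Arg at P1). Fragment-level results are sensitive to these
# encodings; edit this file to match a particular database's behaviour.

trypsin:
  ec: 3.4.21.4
  specs:
    - p1: KR
  exceptions:
    - p1prime: P

chymotrypsin A:
  ec: 3.4.21.1
  specs:
    - p1: FYWLM
  exceptions:
    - p1prime: P

pancreatic elastase:
  ec: 3.4.21.36
  specs:
    - p1: AVGS
  exceptions:
    - p1prime: P

papain:
  ec: 3.4.22.2
  specs:
    - p2: AVLIFWY
      p1: RKGQ
  exceptions:
    - p1prime: P

ficin:
  ec: 3.4.22.3
  specs:
    - p2: AVLIFWY
      p1: FYWAG
  exceptions:
    - p1prime: P

stem bromelain:
  ec: 3.4.22.32
  specs:
    - p2: AVLI
      p1: KRA
  exceptions:
    - p1prime: P

calpain 2:
  ec: 3.4.22.53
  specs:
    - p2: LV
      p1: YMR
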