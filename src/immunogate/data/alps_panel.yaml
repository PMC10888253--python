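# Default 3-tube, 10-color ALPS immunodeficiency panel.
# Channels are (detector, fluorochrome, marker); marker names are the panel
# identity used for cross-reagent transfer, detectors/fluorochromes are
# instrument bookkeeping.
version: "1.0"
tubes:
  - name: ALPS-T
    scatter_channels: {fsc_a: FSC-A, fsc_h: FSC-H, ssc_a: SSC-A}
    time_channel: TIME
    channels:
      - [FL1, FITC, TCRAB]
      - [FL2, PE, TCRGD]
      - [FL3, ECD, CD19]
      - [FL4, PC5.5, CD25]
      - [FL5, PC7, CD127]
      - [FL6, APC, CD3]
      - [FL8, APC-A700, CD8]
      - [FL9, APC-A750, CD4]
      - [FL10, PB, CD45]
  - name: ACT-T
    scatter_channels: {fsc_a: FSC-A, fsc_h: FSC-H, ssc_a: SSC-A}
    time_channel: TIME
    channels:
      - [FL1, FITC, CD45RA]
      - [FL2, PE, CD69]
      - [FL3, ECD, CD45RO]
      - [FL4, PC5.5, PD1]
      - [FL5, PC7, HLADR]
      - [FL6, APC, CD3]
      - [FL8, APC-A700, CD8]
      - [FL9, APC-A750, CD4]
      - [FL10, PB, CD45]
  - name: ALPS-B
    scatter_channels: {fsc_a: FSC-A, fsc_h: FSC-H, ssc_a: SSC-A}
    time_channel: TIME
    channels:
      - [FL1, FITC, KAPPA]
      - [FL2, PE, LAMBDA]
      - [FL3, ECD, IGD]
      - [FL4, PC5.5, CD27]
      - [FL5, PC7, CD19]
      - [FL6, APC, CD3]
      - [FL8, APC-A700, CD5]
      - [FL9, APC-A750, CD56]
      - [FL10, PB, CD45]

# Subset taxonomy: one tree per tube rooted at "lymphocytes".  Lineage nodes
# (level: lineage) are assigned by the classifier; deeper nodes by ordered
# marker-level predicates on cluster phenotype codes (first match wins).
# Predicate atoms: MARKER>=level or MARKER<=level with levels
# negative|dim|partial|positive|bright.
taxonomy:
  ALPS-T:
    - {name: T cells, parent: lymphocytes, level: lineage}
    - {name: B cells, parent: lymphocytes, level: lineage}
    - {name: NK cells, parent: lymphocytes, level: lineage}
    - {name: gd T cells, parent: T cells, predicate: "TCRGD>=positive"}
    - {name: CD4 T cells, parent: T cells, predicate: "CD4>=positive & CD8<=dim"}
    - {name: CD8 T cells, parent: T cells, predicate: "CD8>=positive & CD4<=dim"}
    - {name: DNT cells, parent: T cells, predicate: "CD4<=dim & CD8<=dim"}
    - {name: TCRab+ DNT cells, parent: DNT cells, predicate: "TCRAB>=positive"}
    - {name: Treg-like cells, parent: CD4 T cells, predicate: "CD25>=positive & CD127<=dim"}
  ACT-T:
    - {name: T cells, parent: lymphocytes, level: lineage}
    - {name: non-T lymphocytes, parent: lymphocytes, level: lineage}
    - {name: CD45RA+ T cells, parent: T cells, predicate: "CD45RA>=positive & CD45RO<=dim"}
    - {name: CD45RO+ T cells, parent: T cells, predicate: "CD45RO>=positive & CD45RA<=dim"}
  ALPS-B:
    - {name: T cells, parent: lymphocytes, level: lineage}
    - {name: B cells, parent: lymphocytes, level: lineage}
    - {name: NK cells, parent: lymphocytes, level: lineage}
    - {name: switched memory B cells, parent: B cells, predicate: "CD27>=positive & IGD<=dim"}
    - {name: non-switched memory B cells, parent: B cells, predicate: "CD27>=positive & IGD>=positive"}
    - {name: naive B cells, parent: B cells, predicate: "IGD>=positive & CD27<=dim"}
    - {name: kappa+ B cells, parent: B cells, axis: light_chain, predicate: "KAPPA>=positive & LAMBDA<=dim"}
    - {name: lambda+ B cells, parent: B cells, axis: light_chain, predicate: "LAMBDA>=positive & KAPPA<=dim"}

# Reference ranges are percent-of-denominator bounds.  Only the CD45RA+
# (30-60% of T) and switched-memory-B (>5% of B) ranges are clinically
# sourced; the rest are ILLUSTRATIVE defaults, not clinical values.
reference_ranges:
  CD45RA+ T cells: {low: 30, high: 60, denominator: T cells}
  CD45RO+ T cells: {low: null, high: 60, denominator: T cells, illustrative: true}
  switched memory B cells: {low: 5, high: null, denominator: B cells}

alps_criteria:
  dnt_pct_of_lymphs: 1.5
  dnt_pct_of_cd3: 2.5
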