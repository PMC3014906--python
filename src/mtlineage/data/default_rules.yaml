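# Default classification rules. Override any section and pass the file to
# the classifier or the CLI; omitted sections keep these defaults.
motif_rules:
  - haplogroup: A
    required: [16111T, 16223T, 16290T, 16319A, 16362C]
  - haplogroup: B
    required: [16189C, 16217C]
  - haplogroup: C
    required: [16223T, 16298C, 16325C, 16327T]
  - haplogroup: D
    required: [16223T, 16325C, 16362C]
rflp_markers:
  - haplogroup: A
    site: 663
    enzyme: HaeIII
    polarity: gain
  - haplogroup: B
    special: 9bp-deletion
  - haplogroup: C
    site: 13259
    enzyme: HincII
    polarity: loss
  - haplogroup: D
    site: 5176
    enzyme: AluI
    polarity: loss
  - haplogroup: X
    site: 1715
    enzyme: DdeI
    polarity: loss
coding_panel:
  - subhaplogroup: B2
    positions: {3547: G, 4977: C, 6473: T, 9950: C, 11177: C}
  - subhaplogroup: D1
    positions: {2092: T}
  - subhaplogroup: C
    positions: {14318: C, 15487: T}
  - subhaplogroup: C1
    positions: {14318: C, 15487: T}
    hvsi_addendum: 16325C
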