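# Default excision grammars for the 21 single-copy neuropeptide precursor
# families of Polyneoptera.  One mapping per family:
#   id            family identifier
#   location      post_signal | c_terminal | internal | post_propeptide
#   n_flank       "signal_peptide" or list of basic motifs (alternates per order)
#   c_flank       list of basic motifs; may include "precursor_end"
#   amidated      C-terminal amidation expected (Gly donor before the C-flank)
#   pglu          N-terminal Gln -> pyroglutamate expected
#   length_range  advisory mature-peptide length range in residues
# Optional: retain_post_signal_basics (a KR at the signal boundary is part of
# the mature peptide, not a cleavage site), secondary_site (1-based position of
# an internal potential cleavage site reported as annotation only).
families:
  - id: ACP
    location: post_signal
    n_flank: signal_peptide
    c_flank: [KR]
    amidated: true
    pglu: true
    length_range: [10, 12]
  - id: AST-CC
    location: c_terminal
    n_flank: [RR]
    c_flank: [KR, RR, precursor_end]
    amidated: false
    pglu: false
    length_range: [18, 20]
  - id: AST-CCC
    location: c_terminal
    n_flank: [KR]
    c_flank: [K, KK]
    amidated: true
    pglu: false
    length_range: [14, 14]
  - id: AT
    location: post_propeptide
    n_flank: [R]
    c_flank: [KR]
    amidated: true
    pglu: false
    length_range: [12, 13]
  - id: CCAP
    location: post_propeptide
    n_flank: [KR]
    c_flank: [KKR, RKR]
    amidated: true
    pglu: false
    length_range: [9, 9]
  - id: CCHamide-1
    location: post_signal
    n_flank: signal_peptide
    c_flank: [KR]
    amidated: true
    pglu: false
    length_range: [14, 16]
  - id: CCHamide-2
    location: post_signal
    n_flank: signal_peptide
    c_flank: [KR]
    amidated: true
    pglu: false
    retain_post_signal_basics: true
    length_range: [14, 16]
  - id: CNMamide
    location: c_terminal
    n_flank: [KR, KK]
    c_flank: [RKR]
    amidated: true
    pglu: false
    length_range: [13, 18]
  - id: corazonin
    location: post_signal
    n_flank: signal_peptide
    c_flank: [RKR]
    amidated: true
    pglu: true
    length_range: [9, 11]
  - id: CRF-DH
    location: internal
    n_flank: [KR]
    c_flank: [KR, RKR]
    amidated: true
    pglu: false
    length_range: [42, 46]
  - id: CT-DH
    location: internal
    n_flank: [KR]
    c_flank: [RRRR, RKRR]
    amidated: true
    pglu: false
    length_range: [31, 31]
  - id: elevenin
    location: post_signal
    n_flank: signal_peptide
    c_flank: [KR, RKR, KKR]
    amidated: false
    pglu: false
    length_range: [17, 22]
  - id: HanSolin
    location: c_terminal
    n_flank: [R, RR]
    c_flank: [RR, KR]
    amidated: true
    pglu: false
    length_range: [8, 16]
  - id: MS
    location: c_terminal
    n_flank: [KR]
    c_flank: [RRR]
    amidated: true
    pglu: true
    length_range: [10, 11]
  - id: NPF-1
    location: post_signal
    n_flank: signal_peptide
    c_flank: [KR]
    amidated: true
    pglu: false
    length_range: [30, 36]
  - id: NPF-2
    location: post_signal
    n_flank: signal_peptide
    c_flank: [KR]
    amidated: true
    pglu: false
    length_range: [43, 47]
  - id: proctolin
    location: post_signal
    n_flank: signal_peptide
    c_flank: [R]
    amidated: false
    pglu: false
    length_range: [5, 5]
  - id: RFLamide
    location: c_terminal
    n_flank: [RKR, RRR, RR]
    c_flank: [RRR, RR, RRRR, R]
    amidated: true
    pglu: false
    length_range: [12, 14]
  - id: SIFamide
    location: post_signal
    n_flank: signal_peptide
    c_flank: [KR]
    amidated: true
    pglu: false
    length_range: [11, 14]
  - id: sNPF
    location: internal
    n_flank: [RK]
    c_flank: [RR]
    amidated: true
    pglu: false
    secondary_site: 3
    length_range: [11, 11]
  - id: trissin
    location: post_signal
    n_flank: signal_peptide
    c_flank: [RKR, KKR, KR]
    amidated: false
    pglu: false
    length_range: [26, 28]
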