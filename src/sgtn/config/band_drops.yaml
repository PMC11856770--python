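# Customary water-absorption / noisy band removal lists (0-based indices,
# "lo-hi" ranges inclusive).  The benchmark literature standardizes only the
# retained counts (Indian Pines 220 -> 200, Salinas 224 -> 204); edit these
# lists if your copy of a cube uses a different convention.
indian_pines:
  - "103-107"
  - "149-162"
  - 219
salinas:
  - "107-111"
  - "153-166"
  - 223
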