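# Landmark scheme registry, version 1.
#
# All indices in this file use the 1-based numbering of the published landmark
# definitions for the three carapace views; the loader converts to 0-based
# internal indices. Semilandmark "chains" list, in order along the outline, the
# bounding landmark, the semilandmarks between them, and the closing landmark;
# sliding tangent chords are taken from chain adjacency. For symmetric views,
# "pairs" is the left/right bilateral correspondence (an involution with no
# fixed points) and "midline" lists the sagittal-plane points. The bilateral
# pairing of non-chain landmarks is a canonical choice consistent with the
# chain structure (the published table fixes counts and roles, not an explicit
# pairing).
version: 1
views:
  dorsal:
    n_points: 49
    symmetric: true
    repeatable_pc_count: 5
    midline: [1, 2, 3, 4, 5, 6, 7]
    pairs:
      - [8, 19]
      - [9, 20]
      - [10, 21]
      - [11, 22]
      - [12, 23]
      - [13, 24]
      - [14, 25]
      - [15, 26]
      - [16, 27]
      - [17, 28]
      - [18, 29]
      - [30, 40]
      - [31, 41]
      - [32, 42]
      - [33, 43]
      - [34, 44]
      - [35, 45]
      - [36, 46]
      - [37, 47]
      - [38, 48]
      - [39, 49]
    chains:
      # pleural outline between landmarks 13 and 15 (left) / 24 and 26 (right)
      - [13, 30, 31, 32, 33, 34, 35, 36, 37, 38, 39, 15]
      - [24, 40, 41, 42, 43, 44, 45, 46, 47, 48, 49, 26]
  lateral:
    n_points: 44
    symmetric: false
    repeatable_pc_count: 9
    midline: []
    pairs: []
    chains:
      # carapace outline between landmarks 2 and 3, then 3 and 4
      - [2, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28,
         29, 30, 31, 32, 33, 34, 35, 36, 37, 38, 39, 40, 3]
      - [3, 41, 42, 43, 44, 4]
  posterior:
    n_points: 63
    symmetric: true
    repeatable_pc_count: 13
    midline: [1, 2, 3]
    pairs:
      - [4, 10]
      - [5, 11]
      - [6, 12]
      - [7, 13]
      - [8, 14]
      - [9, 15]
      - [16, 40]
      - [17, 41]
      - [18, 42]
      - [19, 43]
      - [20, 44]
      - [21, 45]
      - [22, 46]
      - [23, 47]
      - [24, 48]
      - [25, 49]
      - [26, 50]
      - [27, 51]
      - [28, 52]
      - [29, 53]
      - [30, 54]
      - [31, 55]
      - [32, 56]
      - [33, 57]
      - [34, 58]
      - [35, 59]
      - [36, 60]
      - [37, 61]
      - [38, 62]
      - [39, 63]
    chains:
      # carapace outline, left arcs: 3-4, 4-5, 5-6; right arcs: 3-10, 10-11, 11-12
      - [3, 16, 17, 18, 19, 20, 21, 22, 23, 4]
      - [4, 24, 25, 26, 27, 28, 29, 30, 31, 5]
      - [5, 32, 33, 34, 35, 36, 37, 38, 39, 6]
      - [3, 40, 41, 42, 43, 44, 45, 46, 47, 10]
      - [10, 48, 49, 50, 51, 52, 53, 54, 55, 11]
      - [11, 56, 57, 58, 59, 60, 61, 62, 63, 12]
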