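"""The four tree-comparison scores on a worked 8-cell example.

Each metric is sensitive to different reconstruction mistakes: RF counts
mismatched splits, TRP compares rooted triplets (and is the only one that
sees a clade re-attached at the wrong height), QRT compares unrooted
quartets, and CLI measures shared clustering information.
"""

import lintracer as lt

truth = lt.parse_newick("(((A,B),(C,D)),((E,F),(G,H)));")
cases = {
    "cousins A,C swapped": lt.parse_newick("(((C,B),(A,D)),((E,F),(G,H)));"),
    "A,E swapped across clades": lt.parse_newick("(((E,B),(C,D)),((A,F),(G,H)));"),
    "(G,H) attached one level higher": lt.parse_newick("((G,H),(((A,B),(C,D)),(E,F)));"),
    "star (no structure at all)": lt.star_tree(list("ABCDEFGH")),
}

print(f"{'reconstruction':35s} {'RF':>5s} {'TRP':>5s} {'QRT':>5s} {'CLI':>5s}")
for name, tree in cases.items():
    r = lt.score_all(truth, tree)
    print(f"{name:35s} {r.rf:5.2f} {r.trp:5.2f} {r.qrt:5.2f} {r.cli:5.2f}")
# Note the third row: the unrooted topology is unchanged, so RF, QRT and CLI
# are all 0 -- only the triplet score (0.29) detects the height error.
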