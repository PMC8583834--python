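"""Bundled worked-example data: the seven-group slipper-orchid panel.

Group codes: A — sect. Coryopedilum, B — sect. Pardalopetalum, C —
sect. Cochlopetalum, D — sect. Barbata, E — sect. Paphiopedilum (the
five ingroup sections of subgenus Paphiopedilum), F — subgen.
Brachypetalum, G — subgen. Parvisepalum (outgroups).

``GROUP_TOPOLOGIES`` holds the support-collapsed, group-level consensus
topologies of the six low-copy nuclear markers and the combined plastid
matrix for this panel; ``CLOCK_MODEL_TABLE`` the stepping-stone log
marginal likelihoods of the strict vs. relaxed clock for each matrix.
They drive the worked examples and the desk-scale acceptance checks.
"""

from __future__ import annotations

#: Support-collapsed group-level topologies (PP < 0.97 collapsed).
GROUP_TOPOLOGIES: dict[str, str] = {
    "XDH": "((((A,B),(C),E),(D),(F)),G);",
    "RAD51": "(((F,C),((A),(B),(E),(D))),G);",
    "PHYC": "((F,(((B),(A),(C)),(E,D))),G);",
    "ACO": "((F,(((A,B),C),(E),(D))),G);",
    "DEF4": "((F,((A,B),(C),(E),(D))),G);",
    "LFY": "((F,(A,B),(E),(C,D)),G);",
    "plastid": "((F,(((A,B),C),(E,D))),G);",
}

#: The reference topology for conflict detection: the plastid tree,
#: congruent with morphology.
REFERENCE_TOPOLOGY: str = GROUP_TOPOLOGIES["plastid"]

#: (matrix, model_a, logml_a, model_b, logml_b): strict vs. relaxed
#: clock log marginal likelihoods per matrix ("B and D" = birth-death
#: tree prior).
CLOCK_MODEL_TABLE: list[tuple[str, str, float, str, float]] = [
    ("ACO", "Relaxed/B and D", -4499.32, "Strict/B and D", -4496.78),
    ("DEF4", "Relaxed/B and D", -3701.28, "Strict/B and D", -3700.92),
    ("PHYC", "Relaxed/B and D", -1665.58, "Strict/B and D", -1662.93),
    ("XDH", "Relaxed/B and D", -2143.99, "Strict/B and D", -2143.49),
    ("LFY", "Strict/B and D", -12001.96, "Relaxed/B and D", -11972.86),
    ("RAD51", "Relaxed/B and D", -2908.64, "Strict/B and D", -2906.61),
    ("plastid", "Strict/B and D", -15868.13, "Relaxed/B and D", -15848.6),
]

#: Reference 2 ln BF values and evidence labels for the table above,
#: at display precision (regression targets for the worked example).
CLOCK_MODEL_EXPECTED: dict[str, tuple[str, str]] = {
    "ACO": ("5.08", "Weak"),
    "DEF4": ("0.72", "Inconclusive"),
    "PHYC": ("5.3", "Weak"),
    "XDH": ("1.0", "Inconclusive"),
    "LFY": ("58.2", "Very strong"),
    "RAD51": ("4.06", "Weak"),
    "plastid": ("39.06", "Very strong"),
}
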