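"""Shared constants: scored markers, published cutoffs, motif communities.

The three physiological markers scored by the D-score system, their stress
directions, and the published Youden cutoffs are fixed by the study design;
everything else in the package treats them as configuration.
"""

from __future__ import annotations

from .phenoscore import MarkerDirection

#: The three scored physiological markers and the direction in which chronic
#: stress moves them. Adrenal hypertrophy raises normalized adrenal weight;
#: thymic involution and blunted growth lower thymus weight and body-weight
#: gain.
SCORED_MARKERS: tuple[MarkerDirection, ...] = (
    MarkerDirection("bw_gain_g", "stress_lower"),
    MarkerDirection("adrenal_norm", "stress_higher"),
    MarkerDirection("thymus_norm", "stress_lower"),
)

#: Published Youden cutoffs for the three markers (g, g/g, g/g). These may be
#: frozen into a run instead of re-deriving cutoffs from the analyzed cohort.
PAPER_CUTOFFS: dict[str, float] = {
    "bw_gain_g": 3.565,
    "adrenal_norm": 1.225e-4,
    "thymus_norm": 1.551e-3,
}

#: Published motif -> community partition for the 38 behavioral motifs.
#: Community ids follow the pruning convention (numbered by smallest member
#: motif), so an exactly recovered partition lines up with these ids; names
#: are applied only through PAPER_COMMUNITY_LABELS, never inferred.
PAPER_COMMUNITIES: dict[int, int] = {
    **{m: 0 for m in (0, 5, 10, 14, 17, 24, 29, 34)},          # walk
    **{m: 1 for m in (1, 6, 9, 12, 15, 19, 21, 26, 27, 28, 36)},  # stat. expl./pause/sniff
    **{m: 2 for m in (2, 7, 13, 31)},                           # groom
    **{m: 3 for m in (3, 4, 11, 18, 23, 30)},                   # rear
    **{m: 4 for m in (8, 22, 25)},                              # other
    **{m: 5 for m in (16, 20, 32)},                             # stationary rotation
    **{m: 6 for m in (33, 37)},                                 # turn
    **{m: 7 for m in (35,)},                                    # dig
}

PAPER_COMMUNITY_LABELS: dict[int, str] = {
    0: "walk",
    1: "stationary_exploration",
    2: "groom",
    3: "rear",
    4: "other",
    5: "stationary_rotation",
    6: "turn",
    7: "dig",
}

#: Published per-group unit counts (units recorded, of which interneurons).
PAPER_UNIT_COUNTS: dict[str, dict[str, int]] = {
    "control": {"total": 301, "interneuron": 16},
    "stress": {"total": 324, "interneuron": 13},
}
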