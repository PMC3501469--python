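"""Default parameter values for the Hood Canal steelhead corridor study.

These constants describe the 2008-2010 acoustic-telemetry study design the
package emulates: receiver-line geometry, published per-line detection
probabilities, per-segment apparent-survival estimates by group and year,
cohort structure, and the fixed terminal-line detection probability with
its 95% confidence bounds. They serve as generating values for the
synthetic-data module and as inputs to internal-consistency checks; none
of them is recomputed from raw telemetry here.
"""

from __future__ import annotations

from .io_model import Population, ReceiverLine, SegmentGeometry

# Occasion lines, ordered seaward. Corridor positions are km along a single
# axis with the Skokomish River mouth at 0.
OCCASION_LINES = ("RM", "HCB", "ADM", "JDF")

#: Terminal-line detection probability fixed in every fit (mean of an
#: independently calibrated receiver line) and its 95% confidence bounds
#: used for the survival sensitivity range.
FIXED_P_JDF = 0.685
FIXED_P_JDF_BOUNDS = (0.428, 0.863)

#: Shared marine-line detection probabilities and per-river-mouth RM
#: detection probabilities (proportions).
DETECTION_P = {
    "RM:BigBeef": 0.928,
    "RM:Duckabush": 0.489,
    "RM:Skokomish": 0.415,
    "HCB": 0.767,
    "ADM": 0.757,
    "JDF": FIXED_P_JDF,
}

#: River-mouth line serving each population.
RM_LINE_OF = {
    Population.BigBeefW: "RM:BigBeef",
    Population.SkokomishW: "RM:Skokomish",
    Population.SkokomishH: "RM:Skokomish",
    Population.DuckabushH: "RM:Duckabush",
}

SEGMENT_NAMES = ("PR-RM", "RM-HCB", "HCB-ADM", "ADM-JDF")

#: Between-line distances (km) by population corridor. PR-RM and RM-HCB
#: vary by river; HCB-ADM and ADM-JDF are shared.
SEGMENT_DISTANCES_KM = {
    Population.BigBeefW: (0.05, 24.0, 25.0, 110.0),
    Population.SkokomishW: (13.5, 75.0, 25.0, 110.0),
    Population.SkokomishH: (13.5, 75.0, 25.0, 110.0),
    Population.DuckabushH: (1.9, 38.0, 25.0, 110.0),
}

#: Published segment survival proportions (PR-RM, RM-HCB, HCB-ADM, ADM-JDF)
#: for each (year, group) row of the year-structured best model. "pooled"
#: groups wild fish (plus the Duckabush hatchery group in 2009); "SkokH" is
#: the Skokomish hatchery group.
SEGMENT_SURVIVAL = {
    (2008, "pooled"): (0.969, 0.892, 0.389, 0.457),
    (2008, "SkokH"): (0.587, 0.341, 0.470, 0.320),
    (2009, "pooled"): (0.961, 0.864, 0.329, 0.393),
    (2009, "SkokH"): (0.522, 0.285, 0.406, 0.266),
    (2010, "pooled"): (0.958, 0.855, 0.312, 0.374),
    (2010, "SkokH"): (0.502, 0.269, 0.387, 0.251),
}

#: Published cumulative marine (RM-JDF) survival, percent, for the same rows.
MARINE_SURVIVAL_PCT = {
    (2008, "pooled"): 15.9,
    (2008, "SkokH"): 5.1,
    (2009, "pooled"): 11.2,
    (2009, "SkokH"): 3.1,
    (2010, "pooled"): 10.0,
    (2010, "SkokH"): 2.6,
}

#: Published QAICc of the two best-ranked candidate models (used for
#: ranking-arithmetic consistency checks) and their parameter counts.
TOP_MODEL_QAICC = (791.771, 791.889)
TOP_MODEL_K = 15

#: Overdispersion estimate applied to the full dataset and the number of
#: released animals (the effective sample size convention used here).
C_HAT = 1.302
N_RELEASED = 302

#: Cohort structure: (year, population) -> (n, mean length mm, SE length,
#: mean weight g, SE weight, release-window day-of-year, mean smolt index).
COHORTS = {
    (2008, Population.BigBeefW): (27, 183, 3, 57.6, 2.6, (107, 128), 2.63),
    (2008, Population.SkokomishW): (41, 180, 3, 53.7, 2.5, (123, 144), 2.46),
    (2008, Population.SkokomishH): (42, 171, 1, 49.0, 1.1, (120, 148), 2.19),
    (2009, Population.BigBeefW): (32, 175, 2, 48.2, 2.4, (114, 130), 2.34),
    (2009, Population.SkokomishW): (23, 175, 4, 50.9, 3.3, (119, 147), 2.22),
    (2009, Population.SkokomishH): (29, 211, 3, 93.5, 3.5, (119, 157), 2.24),
    (2009, Population.DuckabushH): (30, 211, 2, 91.6, 3.2, (150, 157), 3.00),
    (2010, Population.BigBeefW): (36, 178, 2, 50.2, 2.1, (104, 125), 2.80),
    (2010, Population.SkokomishW): (12, 167, 4, 42.6, 3.1, (112, 149), 2.45),
    (2010, Population.SkokomishH): (30, 201, 3, 76.3, 3.6, (112, 120), 1.77),
}

#: Corridor positions (km, Skokomish river mouth = 0, increasing seaward)
#: of each occasion line per population's route.
LINE_POSITIONS_KM = {
    Population.BigBeefW: {"RM:BigBeef": 51.0, "HCB": 75.0, "ADM": 100.0, "JDF": 210.0},
    Population.SkokomishW: {"RM:Skokomish": 0.0, "HCB": 75.0, "ADM": 100.0, "JDF": 210.0},
    Population.SkokomishH: {"RM:Skokomish": 0.0, "HCB": 75.0, "ADM": 100.0, "JDF": 210.0},
    Population.DuckabushH: {"RM:Duckabush": 37.0, "HCB": 75.0, "ADM": 100.0, "JDF": 210.0},
}


def default_geometry(population: Population) -> SegmentGeometry:
    """Segment geometry (PR->RM->HCB->ADM->JDF) for one population."""
    d = SEGMENT_DISTANCES_KM[population]
    rm = RM_LINE_OF[population]
    return SegmentGeometry(
        population=population,
        segments=(
            ("PR", rm, d[0]),
            (rm, "HCB", d[1]),
            ("HCB", "ADM", d[2]),
            ("ADM", "JDF", d[3]),
        ),
    )


def default_receiver_lines(n_behavioral: int = 8) -> list[ReceiverLine]:
    """Occasion lines plus evenly spaced behavioral receivers in Hood Canal.

    Receiver positions use the shared corridor axis; each river mouth is a
    separate occasion-1 line, mirroring the study's line layout.
    """
    lines = [
        ReceiverLine("RM:Skokomish", (("SK-RM-1", 0.0), ("SK-RM-2", 0.0)), 1),
        ReceiverLine("RM:BigBeef", (("BB-RM-1", 51.0), ("BB-RM-2", 51.0)), 1),
        ReceiverLine("RM:Duckabush", (("DK-RM-1", 37.0),), 1),
        ReceiverLine("HCB", tuple((f"HCB-{i}", 75.0) for i in range(1, 8)), 2),
        ReceiverLine("ADM", tuple((f"ADM-{i}", 100.0) for i in range(1, 14)), 3),
        ReceiverLine("JDF", tuple((f"JDF-{i}", 210.0) for i in range(1, 32)), 4),
    ]
    if n_behavioral:
        step = 70.0 / (n_behavioral + 1)
        recvs = tuple(
            (f"HC-B{i}", round(2.0 + i * step, 2)) for i in range(1, n_behavioral + 1)
        )
        lines.append(ReceiverLine("HC-behavior", recvs, None))
    return lines
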