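"""Instrument item catalog for the verbal-abuse / psychopathology / social-interaction study.

Seven self-report instruments are represented:

* VAQ   — verbal abuse questionnaire, 15 items per source (parents, peers,
          supervisors), each item on a 0-8 Likert scale.
* PHQ-9 — depressive symptoms, 9 items, 0-3.
* GAD-7 — generalised anxiety, 7 items, 0-3.
* LSAS  — social anxiety, 8 fear/avoidance sub-domain sums (public speech,
          social interaction with strangers, assertiveness, public interaction).
* SAS   — smartphone addiction, 4 sub-domain sums on a 1-6 item scale.
* CAGE  — alcohol misuse, 4 binary items (total score used in the covariance
          network).
* ASRS  — adult ADHD screener part A, 6 items, 0-4.

Three variable sets are derived from the catalog:

* the *simulated* set — the 83 variables the generator draws directly
  (45 per-source VAQ items + 9 + 7 + 8 + 4 + 4 CAGE items + 6);
* the *severity DAG* set (41 nodes) — 3 per-source VAQ totals plus the
  38 non-VAQ variables, used for the directed network of abuse severity,
  psychopathology and social interaction;
* the *covariance network* set (50 nodes) — 15 source-averaged VAQ items,
  the CAGE total, and the same non-VAQ variables, used for the per-person
  covariance networks.

Target means/SDs are the published cohort marginals (N = 5,616); the
generator's moment calibration reproduces them.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ItemSpec",
    "ItemCatalog",
    "build_item_catalog",
    "VAQ_SOURCES",
    "SOURCE_TOTAL_MOMENTS",
]

VAQ_SOURCES = ("parents", "peers", "supervisors")

#: Per-source VAQ 15-item total-score moments (mean, SD) as published for
#: the severity networks.
SOURCE_TOTAL_MOMENTS = {
    "parents": (3.2, 7.7),
    "peers": (3.3, 7.5),
    "supervisors": (2.6, 6.4),
}

#: Source-specific name prefixes used throughout the study's figures.
_SOURCE_PREFIX = {"parents": "VAPa", "peers": "VAPeer", "supervisors": "VAPro"}

# (item number, label, mean, sd) — source-averaged VAQ item marginals.
_VAQ_ITEMS = [
    (1, "scolded me", 0.66, 0.88),
    (2, "yelled at me", 0.31, 0.61),
    (3, "swore at me", 0.18, 0.48),
    (4, "blamed me for something", 0.30, 0.62),
    (5, "gave me an insult", 0.22, 0.53),
    (6, "threatened to hit me", 0.06, 0.29),
    (7, "used a nickname that gave me insults", 0.10, 0.34),
    (8, "said I was stupid", 0.19, 0.51),
    (9, "blamed me for what I did not do", 0.14, 0.42),
    (10, "humiliated me in front of others", 0.15, 0.42),
    (11, "criticized me", 0.18, 0.48),
    (12, "yelled at me without reason", 0.06, 0.28),
    (13, "told me that I was useless", 0.06, 0.29),
    (14, "made me feel worthless", 0.12, 0.40),
    (15, "raised one's voice", 0.29, 0.59),
]

_PHQ_ITEMS = [
    (1, "low interest or pleasure", 0.37, 0.64),
    (2, "feeling down, hopeless", 0.36, 0.59),
    (3, "trouble sleeping", 0.49, 0.76),
    (4, "tired or little energy", 0.64, 0.78),
    (5, "poor appetite/overeating", 0.34, 0.64),
    (6, "guilt", 0.22, 0.54),
    (7, "trouble concentrating", 0.12, 0.41),
    (8, "moving slowly/restless", 0.06, 0.28),
    (9, "suicidal thoughts", 0.04, 0.24),
]

_GAD_ITEMS = [
    (1, "nervous, anxious, on edge", 0.25, 0.52),
    (2, "uncontrollable worry", 0.23, 0.54),
    (3, "worry about different things", 0.43, 0.70),
    (4, "trouble relaxing", 0.21, 0.52),
    (5, "restless", 0.09, 0.33),
    (6, "irritable", 0.20, 0.47),
    (7, "afraid something awful might happen", 0.09, 0.35),
]

# name, label, n_items (0-3 scale -> bounds 0..3*n), mean, sd
_LSAS_SUBSCORES = [
    ("LSAS1_PS", "fear for public speech", 5, 2.81, 3.24),
    ("LSAS2_PS", "avoidance from public speech", 5, 2.04, 2.67),
    ("LSAS1_SI", "fear for social interaction with strangers", 3, 1.43, 1.91),
    ("LSAS2_SI", "avoidance from social interactions with strangers", 3, 1.20, 1.73),
    ("LSAS1_AST", "fear of assertiveness", 5, 1.66, 2.32),
    ("LSAS2_AST", "avoidance from assertiveness", 5, 1.45, 2.12),
    ("LSAS1_PI", "fear for social interactions at public spaces", 6, 1.75, 2.43),
    ("LSAS2_PI", "avoidance from social interactions at public spaces", 6, 1.96, 2.57),
]

# name, label, n_items (1-6 scale -> bounds n..6*n), mean, sd
_SAS_SUBSCORES = [
    ("SAS_LD", "daily-life disturbance related to smartphone use", 5, 13.90, 6.67),
    ("SAS_PA", "positive anticipation for smartphone use", 8, 13.36, 5.71),
    ("SAS_WD", "withdrawal from smartphone use", 6, 11.67, 5.10),
    ("SAS_CYB", "cyberspace-oriented relationship", 7, 11.47, 4.75),
]

_CAGE_ITEMS = [
    (1, "felt you needed to cut down on your drinking", 0.16, 0.36),
    (2, "people annoyed you by criticizing your drinking", 0.03, 0.17),
    (3, "felt guilty about drinking", 0.07, 0.26),
    (4, "felt you needed a drink as an eye-opener", 0.01, 0.11),
]

_CAGE_TOTAL = (0.27, 0.62)

_ASRS_ITEMS = [
    (1, "trouble wrapping up final details of a project", 0.84, 1.03),
    (2, "difficulty getting things in order for a task requiring organization", 0.63, 0.89),
    (3, "problems remembering appointments or obligations", 0.74, 0.92),
    (4, "avoiding getting started on a task requiring a lot of thought", 1.00, 1.11),
    (5, "fidget or squirm when you have to sit down for a long time", 0.96, 1.15),
    (6, "feel overly active and compelled to do things", 0.63, 0.95),
]


@dataclass(frozen=True)
class ItemSpec:
    """One catalog variable: identity, instrument, Likert bounds, target moments.

    ``derived`` marks variables that the generator does not draw directly
    (source-averaged VAQ items, per-source totals, the CAGE total); they are
    computed from simulated items.  ``integer`` is False for variables whose
    support is not an integer grid (the averaged VAQ items take multiples of
    one third).
    """

    name: str
    label: str
    instrument: str  # VAQ | PHQ9 | GAD7 | LSAS | SAS | CAGE | ASRS
    source: str  # parents | peers | supervisors | none
    min_value: float
    max_value: float
    target_mean: float
    target_sd: float
    integer: bool = True
    derived: bool = False

    def __post_init__(self):
        if not self.min_value < self.max_value:
            raise ValueError(f"{self.name}: min_value must be < max_value")
        if not (self.min_value <= self.target_mean <= self.max_value):
            raise ValueError(f"{self.name}: target_mean outside the support")
        if not self.target_sd > 0:
            raise ValueError(f"{self.name}: target_sd must be positive")


@dataclass(frozen=True)
class ItemCatalog:
    """The full study catalog with the three variable-set views."""

    simulated: tuple[ItemSpec, ...]  # 83 generator variables
    severity_dag: tuple[ItemSpec, ...]  # 41 nodes (3 VAQ totals + 38 others)
    covariance_net: tuple[ItemSpec, ...]  # 50 nodes (15 VAQ-avg + CAGE total + 34)

    @property
    def network2(self) -> tuple[ItemSpec, ...]:
        """Alias: the 41-node severity DAG variable set."""
        return self.severity_dag

    @property
    def network3(self) -> tuple[ItemSpec, ...]:
        """Alias: the 50-node covariance-network variable set."""
        return self.covariance_net

    def vaq_items(self, source: str) -> tuple[ItemSpec, ...]:
        """The 15 simulated VAQ items of one source, in item order."""
        return tuple(
            s for s in self.simulated if s.instrument == "VAQ" and s.source == source
        )

    def by_name(self, name: str) -> ItemSpec:
        for spec in self.simulated + self.severity_dag + self.covariance_net:
            if spec.name == name:
                return spec
        raise KeyError(name)


def _shared_items() -> list[ItemSpec]:
    """The 34 non-VAQ, non-CAGE-aggregation variables common to both networks."""
    out: list[ItemSpec] = []
    for no, label, m, s in _PHQ_ITEMS:
        out.append(ItemSpec(f"PHQ_{no:02d}", label, "PHQ9", "none", 0, 3, m, s))
    for no, label, m, s in _GAD_ITEMS:
        out.append(ItemSpec(f"GAD_{no:02d}", label, "GAD7", "none", 0, 3, m, s))
    for name, label, k, m, s in _LSAS_SUBSCORES:
        out.append(ItemSpec(name, label, "LSAS", "none", 0, 3 * k, m, s))
    for name, label, k, m, s in _SAS_SUBSCORES:
        out.append(ItemSpec(name, label, "SAS", "none", k, 6 * k, m, s))
    for no, label, m, s in _ASRS_ITEMS:
        out.append(ItemSpec(f"AD_{no:02d}", label, "ASRS", "none", 0, 4, m, s))
    return out


def _per_source_vaq() -> list[ItemSpec]:
    """Per-source VAQ items with the averaged profile rescaled per source.

    Only source-averaged item moments and per-source 15-item total moments are
    published.  Item means are scaled so each source's expected total equals
    the published total mean; item SDs are scaled by the source total SD
    relative to the mean of the three total SDs.
    """
    mean_profile_total = sum(m for _, _, m, _ in _VAQ_ITEMS)
    mean_total_sd = sum(sd for _, sd in SOURCE_TOTAL_MOMENTS.values()) / 3
    out: list[ItemSpec] = []
    for source in VAQ_SOURCES:
        tot_mean, tot_sd = SOURCE_TOTAL_MOMENTS[source]
        mean_scale = tot_mean / mean_profile_total
        sd_scale = tot_sd / mean_total_sd
        prefix = _SOURCE_PREFIX[source]
        for no, label, m, s in _VAQ_ITEMS:
            out.append(
                ItemSpec(
                    f"{prefix}_{no:02d}",
                    label,
                    "VAQ",
                    source,
                    0,
                    8,
                    m * mean_scale,
                    s * sd_scale,
                )
            )
    return out


def build_item_catalog() -> ItemCatalog:
    """Build the full item catalog and its variable-set views.

    Returns an :class:`ItemCatalog` whose ``simulated`` view has 83 entries,
    ``severity_dag`` (network 2) 41 entries and ``covariance_net`` (network 3)
    50 entries.
    """
    shared = _shared_items()
    cage_items = [
        ItemSpec(f"CAGE_no_{no}", label, "CAGE", "none", 0, 1, m, s)
        for no, label, m, s in _CAGE_ITEMS
    ]
    simulated = _per_source_vaq() + [
        s for s in shared if s.instrument in ("PHQ9", "GAD7", "LSAS")
    ] + [s for s in shared if s.instrument == "SAS"] + cage_items + [
        s for s in shared if s.instrument == "ASRS"
    ]

    totals = [
        ItemSpec(
            f"{_SOURCE_PREFIX[src]}_total",
            f"total score of VAQ sourced from {src}",
            "VAQ",
            src,
            0,
            120,
            *SOURCE_TOTAL_MOMENTS[src],
            derived=True,
        )
        for src in VAQ_SOURCES
    ]
    severity_dag = totals + [s for s in shared if s.instrument in ("PHQ9", "GAD7", "LSAS", "SAS")] + cage_items + [
        s for s in shared if s.instrument == "ASRS"
    ]

    vaq_avg = [
        ItemSpec(
            f"VAQavg_{no:02d}", label, "VAQ", "none", 0, 8, m, s,
            integer=False, derived=True,
        )
        for no, label, m, s in _VAQ_ITEMS
    ]
    cage_total = ItemSpec(
        "CAGE_total", "total score of CAGE", "CAGE", "none", 0, 4,
        *_CAGE_TOTAL, derived=True,
    )
    covariance_net = vaq_avg + [
        s for s in shared if s.instrument in ("PHQ9", "GAD7", "LSAS", "SAS")
    ] + [cage_total] + [s for s in shared if s.instrument == "ASRS"]

    # internal consistency of the three views
    assert len(simulated) == 83
    assert len(severity_dag) == 41
    assert len(covariance_net) == 50
    return ItemCatalog(tuple(simulated), tuple(severity_dag), tuple(covariance_net))
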