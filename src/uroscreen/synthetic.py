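"""Synthetic zero-inflated abundance profiles.

The generator emulates the statistical structure of an untargeted GC-MS
urine peak table: per-cell Bernoulli detection times a log-normal abundance,
with a hard instrument detection limit below which values are censored to
zero.  A small set of planted "marker" compounds is strongly detected and
up-shifted in cases while nearly absent from controls; "contaminant"
compounds are high-detection instrument-background species with identical
distributions in both groups.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datamodel import CASE, CONTROL, CompoundRecord, ProfileMatrix

# plausible GC-MS background species used for planted contaminants
_CONTAMINANT_NAMES = [
    "Hexamethylcyclotrisiloxane",
    "Octamethylcyclotetrasiloxane",
    "Decamethylcyclopentasiloxane",
    "Dodecamethylcyclohexasiloxane",
    "Trimethylsilanol",
    "Bis(trimethylsilyl) ether",
    "Diethyl phthalate",
    "Dibutyl phthalate",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the zero-inflated log-normal profile generator.

    Abundances are in arbitrary instrument units (integrated peak areas).
    ``log_mu``/``log_sigma`` parameterise the natural-log scale of the
    baseline log-normal; ``marker_log_shift`` is the additive log-scale
    effect for planted markers in cases (3.0 = three log-sd at the default
    ``log_sigma``).  ``detect_p_*`` are per-cell Bernoulli detection
    probabilities; any surviving value below ``detection_limit`` is censored
    to 0, standing in for the instrument's peak-area reporting cutoff.
    """

    n_case: int = 63
    n_control: int = 61
    m_compounds: int = 922
    n_markers: int = 8
    n_contaminants: int = 8
    log_mu: float = 8.0
    log_sigma: float = 1.0
    marker_log_shift: float = 3.0
    detect_p_case: float = 0.9
    detect_p_control_marker: float = 0.02
    detect_p_background: float = 0.5
    detect_p_contaminant: float = 0.95
    detection_limit: float = 700.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one case and one control sample")
        if self.n_markers + self.n_contaminants > self.m_compounds:
            raise ValueError(
                "n_markers + n_contaminants exceeds m_compounds "
                f"({self.n_markers} + {self.n_contaminants} > {self.m_compounds})"
            )
        for name in (
            "detect_p_case",
            "detect_p_control_marker",
            "detect_p_background",
            "detect_p_contaminant",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")
        if self.log_sigma <= 0:
            raise ValueError("log_sigma must be positive")


def paper_like(**overrides) -> SyntheticConfig:
    """The default study-shaped preset: 63 cases vs 61 controls, 922
    compounds, 8 planted markers and 8 contaminants."""
    return SyntheticConfig(**overrides)


def generate_profile(
    cfg: SyntheticConfig,
) -> tuple[ProfileMatrix, frozenset[str]]:
    """Draw one synthetic profile; returns (profile, planted marker ids).

    Fully seeded: the same config (including seed) is bit-identical.
    Planted markers and contaminants occupy disjoint, randomly placed
    compound rows; all remaining compounds are i.i.d. background with the
    same distribution in both groups.
    """
    rng = np.random.default_rng(cfg.seed)
    m, n = cfg.m_compounds, cfg.n_case + cfg.n_control
    groups = np.array([CASE] * cfg.n_case + [CONTROL] * cfg.n_control, dtype=object)
    case_mask = groups == CASE

    positions = rng.permutation(m)
    marker_rows = np.sort(positions[: cfg.n_markers])
    contaminant_rows = np.sort(positions[cfg.n_markers : cfg.n_markers + cfg.n_contaminants])

    # log-normal abundance for every cell; markers shifted in cases only
    log_abund = rng.normal(cfg.log_mu, cfg.log_sigma, size=(m, n))
    log_abund[np.ix_(marker_rows, np.flatnonzero(case_mask))] += (
        cfg.marker_log_shift * cfg.log_sigma
    )
    abundance = np.exp(log_abund)

    detect_p = np.full((m, n), cfg.detect_p_background)
    detect_p[marker_rows[:, None], :] = np.where(
        case_mask, cfg.detect_p_case, cfg.detect_p_control_marker
    )
    detect_p[contaminant_rows[:, None], :] = cfg.detect_p_contaminant
    detected = rng.random(size=(m, n)) < detect_p

    abundance *= detected
    abundance[abundance < cfg.detection_limit] = 0.0

    marker_set = set(marker_rows)
    contaminant_set = set(contaminant_rows)
    compounds = []
    n_contam_named = 0
    for i in range(m):
        cid = f"C{i:04d}"
        mass = int(rng.integers(70, 400))
        if i in contaminant_set:
            name = _CONTAMINANT_NAMES[n_contam_named % len(_CONTAMINANT_NAMES)]
            n_contam_named += 1
            compounds.append(
                CompoundRecord(cid, name, mass, metabolite="unknown", is_contaminant=True)
            )
        else:
            name = f"Compound {i:04d}, TMS derivative"
            compounds.append(CompoundRecord(cid, name, mass, metabolite="unknown"))

    sample_ids = [f"BC{i + 1:03d}" for i in range(cfg.n_case)] + [
        f"HE{i + 1:03d}" for i in range(cfg.n_control)
    ]
    pm = ProfileMatrix(compounds, sample_ids, groups, abundance)
    planted = frozenset(f"C{i:04d}" for i in marker_rows)
    return pm, planted
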