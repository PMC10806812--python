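"""Prediction models and the criterion-failure diagnosis.

Two fast prediction models rank candidate ligands:

* **PM1** (the design criterion): fitness = ``-r(Ru=CH2)`` of the
  14-electron methylidene complex; shorter bonds are predicted to mean
  more productive catalysts.
* **PM2** (productivity): the mean, over ancillary ligands
  L' = PMe3, H2O, CH2O, of the enthalpic gap between the 16-electron
  adduct Ru8.L' and the unsubstituted metallacyclobutane Ru9.  Ligands
  with ortho carbonyl groups (acetyl/ester) form ancillary bonds to the
  metal that lie outside the model's training domain; for them the
  model refuses with the distinct value :data:`ND`.

The diagnosis compares these predictions with the "true" (surrogate or
deposited-DFT) energetic span -- the free-energy gap between the
resting state and the cycloreversion transition state Ru21 -- and flags
the regime where the resting state has switched away from the
16-electron adduct assumed by the prediction models, which is where the
distance criterion stops ranking catalysts correctly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .energetics import (
    ADDUCT_LIGANDS,
    Descriptors,
    EnergyProfile,
    RESTING_CANDIDATES,
    SubstituentParams,
    compute_descriptors,
    resting_state_of,
)
from .fragments import LigandGraph, canonical_key

__all__ = [
    "ND",
    "FitnessRecord",
    "DiagnosisReport",
    "pm1_fitness",
    "pm2_productivity",
    "resting_state",
    "energetic_span",
    "make_fitness_record",
    "diagnose_criterion",
    "load_free_energies",
]


class _NotDeterminable:
    """Sentinel for predictions outside the model domain.

    Propagates as a distinct value (never as zero or a number); sorts
    below every float in fitness comparisons.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ND"

    def __bool__(self) -> bool:
        return False


ND = _NotDeterminable()


def pm1_fitness(profile: EnergyProfile) -> float:
    """Design-criterion fitness: the negative methylidene bond length."""
    return -profile.r_ruch2


def pm2_productivity(
    profile: EnergyProfile,
    ligand: Optional[LigandGraph] = None,
    params: Optional[SubstituentParams] = None,
    descriptors: Optional[Descriptors] = None,
):
    """Productivity P = mean over L' of (H[Ru8.L'] - H[Ru9]), in kcal/mol.

    H[Ru9] is the MCB stability on the same enthalpic scale
    (``profile.dE_mcb``).  Returns :data:`ND` when the ligand carries
    ortho carbonyl substituents (ancillary-binding regime).  The ligand
    (or its precomputed descriptors) is needed only for that domain
    check; omitting both skips it.
    """
    missing = [lp for lp in ADDUCT_LIGANDS if lp not in profile.h_adduct]
    if missing:
        raise KeyError(f"adduct enthalpies missing for {missing}")
    if descriptors is None and ligand is not None:
        if params is None:
            raise ValueError("SubstituentParams needed to check the PM2 domain")
        descriptors = compute_descriptors(ligand, params)
    if descriptors is not None and descriptors.n_carbonyl_ortho > 0:
        return ND
    return float(
        np.mean([profile.h_adduct[lp] for lp in ADDUCT_LIGANDS]) - profile.dE_mcb
    )


def resting_state(
    profile: EnergyProfile | Mapping[str, float],
    candidates: Sequence[str] = RESTING_CANDIDATES,
) -> str:
    """Most stable candidate state (precursor, phosphine adduct, MCB)."""
    g_rel = profile.g_rel if isinstance(profile, EnergyProfile) else profile
    return resting_state_of(g_rel, candidates)


def energetic_span(
    profile: EnergyProfile | Mapping[str, float],
    candidates: Sequence[str] = RESTING_CANDIDATES,
) -> float:
    """Free-energy span dG = G(Ru21) - G(resting state), kcal/mol.

    Ru21 (cycloreversion of the substituted MCB) is the turnover-
    determining transition state; it follows the resting state within
    one cycle, so no reaction-energy correction applies.
    """
    if isinstance(profile, EnergyProfile):
        g_rel = profile.g_rel
        rest = profile.resting_state or resting_state(g_rel, candidates)
    else:
        g_rel = profile
        rest = resting_state(g_rel, candidates)
    if "Ru21" not in g_rel:
        raise KeyError("G(Ru21) absent from profile")
    return float(g_rel["Ru21"] - g_rel[rest])


# ---------------------------------------------------------------------- #
# Records and diagnosis
# ---------------------------------------------------------------------- #


@dataclass(frozen=True)
class FitnessRecord:
    """Predictions and ground truth for one candidate."""

    key: str
    pm1_fitness: float
    pm2_productivity: object  # float or ND
    span: float
    resting_state: str
    nd_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.pm2_productivity is ND) != (self.nd_reason is not None):
            raise ValueError("pm2 is ND exactly when nd_reason is set")
        if self.span < 0:
            raise ValueError(f"negative energetic span {self.span}")


def make_fitness_record(
    ligand: LigandGraph,
    profile: EnergyProfile,
    params: SubstituentParams,
    key: Optional[str] = None,
) -> FitnessRecord:
    d = compute_descriptors(ligand, params)
    p = pm2_productivity(profile, descriptors=d)
    return FitnessRecord(
        key=key if key is not None else canonical_key(ligand),
        pm1_fitness=pm1_fitness(profile),
        pm2_productivity=p,
        span=energetic_span(profile),
        resting_state=profile.resting_state,
        nd_reason="carbonyl ancillary binding" if p is ND else None,
    )


@dataclass(frozen=True)
class DiagnosisReport:
    """How well the design criterion tracks the true span.

    ``rank_correlation`` is the Spearman correlation between PM1
    fitness and ``-span`` (higher fitness should mean lower barrier).
    The divergence flag is set when the correlation over candidates
    whose resting state is *not* the assumed 16-electron adduct falls
    below the adduct-resting correlation by more than ``margin``.
    """

    n: int
    rank_correlation: Optional[float]
    corr_adduct: Optional[float]
    corr_non_adduct: Optional[float]
    frac_non_adduct: float
    resting_counts: Mapping[str, int]
    divergence: bool
    margin: float
    note: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "rank_correlation": self.rank_correlation,
            "corr_adduct": self.corr_adduct,
            "corr_non_adduct": self.corr_non_adduct,
            "frac_non_adduct": self.frac_non_adduct,
            "resting_counts": dict(self.resting_counts),
            "divergence": self.divergence,
            "margin": self.margin,
            "note": self.note,
        }


def _spearman(f: np.ndarray, s: np.ndarray) -> Optional[float]:
    if len(f) < 2 or np.ptp(f) == 0 or np.ptp(s) == 0:
        return None
    rho = stats.spearmanr(f, s).statistic
    return None if np.isnan(rho) else float(rho)


ADDUCT_STATE = "Ru8·PMe3"


def diagnose_criterion(
    records: Sequence[FitnessRecord],
    margin: float = 0.3,
) -> DiagnosisReport:
    """Rank-correlation diagnosis of the distance criterion.

    Raises on an all-ND population; a degenerate population (identical
    records) yields an undefined correlation reported as ``None``.
    """
    if records and all(r.pm2_productivity is ND for r in records):
        raise ValueError("all-ND population: nothing to diagnose")
    usable = [r for r in records if isinstance(r.pm1_fitness, (int, float))]
    if len(usable) < 2:
        raise ValueError("need at least two records with numeric fitness and span")

    fit = np.array([r.pm1_fitness for r in usable])
    perf = -np.array([r.span for r in usable])
    rho = _spearman(fit, perf)

    is_adduct = np.array([r.resting_state == ADDUCT_STATE for r in usable])
    corr_a = _spearman(fit[is_adduct], perf[is_adduct])
    corr_na = _spearman(fit[~is_adduct], perf[~is_adduct])
    # the criterion has diverged when the non-adduct-resting candidates
    # correlate distinctly worse than the adduct-resting ones, or when
    # resting states switched and the overall ranking inverted outright
    divergence = (
        corr_a is not None and corr_na is not None and corr_na < corr_a - margin
    ) or (bool(is_adduct.size) and not is_adduct.all() and rho is not None and rho < 0)

    counts: dict[str, int] = {}
    for r in usable:
        counts[r.resting_state] = counts.get(r.resting_state, 0) + 1

    return DiagnosisReport(
        n=len(usable),
        rank_correlation=rho,
        corr_adduct=corr_a,
        corr_non_adduct=corr_na,
        frac_non_adduct=float(np.mean(~is_adduct)),
        resting_counts=counts,
        divergence=divergence,
        margin=margin,
        note="rank correlation undefined (degenerate input)" if rho is None else None,
    )


# ---------------------------------------------------------------------- #
# External free-energy tables
# ---------------------------------------------------------------------- #


def load_free_energies(path) -> dict[str, float]:
    """Parse a tabulated stationary-point table (columns: state, G) so
    deposited free energies can feed resting_state / energetic_span."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    state_col, g_col = cols.get("state"), cols.get("g") or cols.get("g_kcal")
    if state_col is None or g_col is None:
        raise ValueError("expected columns 'state' and 'G' (kcal/mol)")
    return {str(row[state_col]): float(row[g_col]) for _, row in df.iterrows()}
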