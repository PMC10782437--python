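"""Boltzmann selectivity objective over a panel of binding pockets.

The objective score of a candidate molecule is the fraction of molecules
bound to the *target* pocket in a canonical ensemble whose states are the
target pocket, a set of structurally homologous off-target pockets, and an
artificial "anybind" sink state:

    P = exp(-beta * e_target) / Z
    Z = exp(-beta * e_target) + sum_j exp(-beta * e_offtarget_j)
        + exp(-beta * e_anybind)

with ``beta = 1 / (k * T)``.  Energies are predicted binding free energies
in kcal/mol (more negative = more favorable).  The anybind sink penalizes
molecules that bind the target only weakly: unless the target energy is
well below the anybind energy, the sink soaks up most of the ensemble and
the score stays low.

When experimental dissociation constants are available instead of docking
energies, the same objective reduces to a ratio of inverse Kd values over
the pockets with reported measurements (the anybind and unreported terms
being negligible for potent binders):

    P ~= (1 / Kd_target) / sum_i (1 / Kd_i)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "PocketPanel",
    "EnergyProfile",
    "ScoreConfig",
    "AffinityPanel",
    "boltzmann_score",
    "kd_score",
    "energy_from_kd",
    "calibrate_anybind",
    "is_hit",
    "read_energy_table",
    "write_energy_table",
    "read_kd_table",
]

#: Gas constant in kcal/(mol*K); kT = 0.61603 kcal/mol at 310 K.
GAS_CONSTANT_KCAL = 1.9872e-3


@dataclass(frozen=True)
class PocketPanel:
    """The target pocket and its ordered homologous off-target pockets."""

    target_id: str
    off_target_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "off_target_ids", tuple(self.off_target_ids))
        ids = (self.target_id,) + self.off_target_ids
        if len(set(ids)) != len(ids):
            raise ValueError(f"pocket identifiers must be unique, got {ids}")

    @property
    def all_ids(self) -> tuple[str, ...]:
        return (self.target_id,) + self.off_target_ids


#: The FLT3 ATP-site panel (gilteritinib-bound conformation) with the five
#: most similar kinase pockets as off-targets.
FLT3_PANEL = PocketPanel(
    target_id="FLT3",
    off_target_ids=("CKIT", "PDGFRA", "VEGFR2", "MK2", "JAK2"),
)


@dataclass(frozen=True)
class EnergyProfile:
    """Per-pocket predicted binding free energies (kcal/mol) for one molecule."""

    energies: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "energies", dict(self.energies))
        for pocket, e in self.energies.items():
            if not math.isfinite(e):
                raise ValueError(f"non-finite energy for pocket {pocket!r}: {e}")

    def __getitem__(self, pocket: str) -> float:
        try:
            return self.energies[pocket]
        except KeyError:
            raise KeyError(f"no energy recorded for pocket {pocket!r}") from None

    def covers(self, panel: PocketPanel) -> bool:
        return all(p in self.energies for p in panel.all_ids)


@dataclass(frozen=True)
class ScoreConfig:
    """Thermodynamic and pipeline constants for the selectivity objective.

    Parameters
    ----------
    temperature_K
        Absolute temperature of the ensemble (default 310 K, body temperature).
    k_boltzmann
        Gas constant in kcal/(mol*K).
    anybind_energy
        Energy of the artificial sink state, kcal/mol.  Calibrated to
        1 kcal/mol below the mean target energy of random samples
        (-6.0 for the FLT3 panel).
    hit_threshold
        A molecule is a hit when its score strictly exceeds this (0.5).
    seed_threshold
        Acquisition optimization is seeded near history points whose score
        strictly exceeds this (0.4).
    invalid_energy
        Placeholder energy assigned to every pocket when a latent point
        decodes to a molecule that cannot be scored (-5.0 kcal/mol): it
        yields a low, constant objective that discourages re-exploration.
    """

    temperature_K: float = 310.0
    k_boltzmann: float = GAS_CONSTANT_KCAL
    anybind_energy: float = -6.0
    hit_threshold: float = 0.5
    seed_threshold: float = 0.4
    invalid_energy: float = -5.0

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")
        if self.k_boltzmann <= 0:
            raise ValueError("k_boltzmann must be positive")
        if not (0 < self.seed_threshold < self.hit_threshold < 1):
            raise ValueError(
                "thresholds must satisfy 0 < seed_threshold < hit_threshold < 1"
            )

    @property
    def kT(self) -> float:
        return self.k_boltzmann * self.temperature_K

    @property
    def beta(self) -> float:
        return 1.0 / self.kT


@dataclass(frozen=True)
class AffinityPanel:
    """Per-pocket dissociation constants (nM); pockets without a reported
    value are simply absent."""

    kds: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "kds", dict(self.kds))
        for pocket, kd in self.kds.items():
            if not (kd > 0 and math.isfinite(kd)):
                raise ValueError(f"Kd for pocket {pocket!r} must be positive, got {kd}")


def boltzmann_score(
    profile: EnergyProfile,
    panel: PocketPanel,
    config: ScoreConfig = ScoreConfig(),
    weights: Mapping[str, float] | None = None,
) -> float:
    """Canonical-ensemble fraction bound to the target pocket.

    Computed with a log-sum-exp shift so that strongly favorable energies
    (down to -100 kcal/mol and beyond) do not overflow.

    Parameters
    ----------
    weights
        Optional per-pocket Boltzmann weights (e.g. protein abundances);
        defaults to equal weighting of every pocket and the anybind sink.
    """
    missing = [p for p in panel.all_ids if p not in profile.energies]
    if missing:
        raise KeyError(f"profile missing energies for pockets: {missing}")
    ids = list(panel.all_ids)
    energies = np.array([profile[p] for p in ids] + [config.anybind_energy])
    if not np.all(np.isfinite(energies)):
        raise ValueError("all energies must be finite")
    w = np.ones_like(energies)
    if weights is not None:
        for i, p in enumerate(ids):
            w[i] = weights.get(p, 1.0)
        w[-1] = weights.get("anybind", 1.0)
    log_terms = -config.beta * energies + np.log(w)
    return float(np.exp(log_terms[0] - logsumexp(log_terms)))


def kd_score(affinities: AffinityPanel, panel: PocketPanel) -> float:
    """Kd-ratio approximation of the selectivity objective.

    Sums 1/Kd over the target and every off-target with a reported value;
    unreported off-targets and the anybind sink contribute nothing.  With a
    single reported pocket (the target) the score is exactly 1.
    """
    if panel.target_id not in affinities.kds:
        raise KeyError(f"target pocket {panel.target_id!r} has no reported Kd")
    extra = set(affinities.kds) - set(panel.all_ids)
    if extra:
        raise KeyError(f"Kd reported for pockets outside the panel: {sorted(extra)}")
    inv = [1.0 / affinities.kds[panel.target_id]]
    inv += [1.0 / affinities.kds[p] for p in panel.off_target_ids if p in affinities.kds]
    return inv[0] / math.fsum(inv)


def energy_from_kd(kd_nM: float, config: ScoreConfig = ScoreConfig()) -> float:
    """Binding free energy (kcal/mol, 1 M standard state) from a Kd in nM.

    ``dG = kT * ln(Kd)`` with Kd expressed in mol/L, so sub-molar constants
    give negative (favorable) energies.
    """
    if not (kd_nM > 0 and math.isfinite(kd_nM)):
        raise ValueError(f"Kd must be positive and finite, got {kd_nM}")
    return config.kT * math.log(kd_nM * 1e-9)


def calibrate_anybind(target_energies: Sequence[float]) -> float:
    """Anybind sink energy: 1 kcal/mol below the mean target energy observed
    when sampling the latent space at random."""
    if len(target_energies) == 0:
        raise ValueError("need at least one target energy to calibrate anybind")
    arr = np.asarray(target_energies, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("target energies must be finite")
    return float(arr.mean() - 1.0)


def is_hit(score: float, config: ScoreConfig = ScoreConfig()) -> bool:
    """True iff the score strictly exceeds the hit threshold."""
    return score > config.hit_threshold


# ---------------------------------------------------------------------------
# CSV interfaces


def read_energy_table(path, panel: PocketPanel) -> pd.DataFrame:
    """Read a wide energy table: columns ``molecule_id, <pocket...>[, score]``."""
    df = pd.read_csv(path)
    missing = [p for p in panel.all_ids if p not in df.columns]
    if missing:
        raise ValueError(f"energy table missing pocket columns: {missing}")
    return df


def write_energy_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_kd_table(path, panel: PocketPanel) -> dict[str, AffinityPanel]:
    """Read a Kd table in long (``molecule_id, pocket, kd_nM``) or wide
    (``molecule_id, <pocket...>``) form; blank wide cells mean unreported.

    Returns a mapping molecule_id -> AffinityPanel.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    out: dict[str, AffinityPanel] = {}
    if {"molecule_id", "pocket", "kd_nM"} <= cols:
        for mol, grp in df.groupby("molecule_id", sort=False):
            out[str(mol)] = AffinityPanel(
                dict(zip(grp["pocket"].astype(str), grp["kd_nM"].astype(float)))
            )
    else:
        pockets = [p for p in panel.all_ids if p in cols]
        if not pockets:
            raise ValueError("Kd table has neither long-form columns nor pocket columns")
        for _, row in df.iterrows():
            kds = {p: float(row[p]) for p in pockets if pd.notna(row[p])}
            out[str(row["molecule_id"])] = AffinityPanel(kds)
    return out


def score_energy_table(
    df: pd.DataFrame,
    panel: PocketPanel,
    config: ScoreConfig = ScoreConfig(),
) -> pd.DataFrame:
    """Append/overwrite a ``score`` column computed from the pocket columns."""
    out = df.copy()
    out["score"] = [
        boltzmann_score(
            EnergyProfile({p: float(row[p]) for p in panel.all_ids}), panel, config
        )
        for _, row in df.iterrows()
    ]
    return out
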