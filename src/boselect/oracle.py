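"""Decode-and-dock oracles: the black-box evaluation contract, invalid and
duplicate semantics, a fully synthetic oracle for desk-scale testing, and
adapter interfaces for a real decoder and docking engine.

The pipeline treats molecule evaluation as a black box: a latent point is
decoded to a molecule identity (deterministically, many latent points per
molecule), and the molecule is scored against every pocket of the panel.
Around 1% of decodes yield molecules that cannot be embedded in 3-D and so
cannot be docked; these are flagged invalid and the caller assigns a fixed
unfavorable energy to every pocket.

The synthetic oracle emulates this contract without any chemistry: decode
identity is the index of the quantization cell containing the latent point,
a hash of that identity marks a configurable fraction of cells invalid, and
per-pocket energies come from smooth multimodal Gaussian-well landscapes
evaluated at the cell center plus reproducible noise.  The target pocket
receives at least one "selective" well that no off-target well overlaps, so
regions of high selectivity score exist by construction.  Search-phase and
validation-phase docking effort (exhaustiveness 8 vs 64 in a real engine)
map to a high and a low noise standard deviation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Protocol, Sequence

import numpy as np

from .scoring import EnergyProfile, PocketPanel, ScoreConfig, boltzmann_score

__all__ = [
    "OracleResult",
    "Oracle",
    "SyntheticLandscapeConfig",
    "SyntheticOracle",
    "make_synthetic_oracle",
    "apply_invalid_rule",
    "rescore",
    "AdapterError",
    "DecoderAdapter",
    "DockingAdapter",
]


class AdapterError(RuntimeError):
    """An adapter failed (engine crash, missing receptor file, ...).

    Distinct from an *invalid molecule*, which is a normal, expected
    outcome carried by ``OracleResult.valid``.
    """


@dataclass(frozen=True)
class OracleResult:
    """Outcome of one decode-and-dock evaluation.

    ``identity`` is a canonical molecule identifier: canonical SMILES for
    real adapters, a quantization-cell index string for the synthetic
    oracle.  ``energies`` is present iff ``valid``.
    """

    identity: str
    valid: bool
    energies: EnergyProfile | None = None

    def __post_init__(self) -> None:
        if self.valid and self.energies is None:
            raise ValueError("a valid result must carry energies")


class Oracle(Protocol):
    """Evaluation contract: latent point -> molecule identity + energies."""

    panel: PocketPanel

    def evaluate(self, latent: np.ndarray) -> OracleResult: ...


@dataclass(frozen=True)
class SyntheticLandscapeConfig:
    """Shape of the synthetic decode-and-dock landscape.

    Each pocket's energy surface is a flat baseline plus Gaussian wells:
    ``E_p(z) = baseline + sum_w depth_pw * exp(-|z - c_pw|^2 / (2 width^2))``
    with depths drawn from ``well_depth_range`` (kcal/mol, negative =
    favorable).  ``quantization_step`` sets the decode granularity: all
    latent points in one cell decode to the same identity, and energies
    are evaluated at the cell center, so they are a property of the
    molecule rather than of the exact latent point.
    """

    dim: int = 4
    n_wells_per_pocket: int = 3
    n_selective_wells: int = 1
    well_depth_range: tuple[float, float] = (-10.0, -6.0)
    baseline_energy: float = -4.5
    well_width: float = 0.45
    quantization_step: float = 0.25
    invalid_fraction: float = 0.01
    noise_sd: float = 0.3
    validation_noise_sd: float = 0.075
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.invalid_fraction < 0.2):
            raise ValueError("invalid_fraction must be in [0, 0.2)")
        if self.quantization_step <= 0:
            raise ValueError("quantization_step must be positive")
        if not (self.noise_sd >= self.validation_noise_sd >= 0):
            raise ValueError("need noise_sd >= validation_noise_sd >= 0")


def _stable_hash_unit(text: str, salt: int) -> float:
    """Deterministic hash of a string to [0, 1), stable across processes."""
    digest = hashlib.sha256(f"{salt}:{text}".encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


@dataclass
class SyntheticOracle:
    """Synthetic decode-and-dock oracle over Gaussian-well landscapes."""

    cfg: SyntheticLandscapeConfig
    panel: PocketPanel
    noise_sd: float
    centers: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    depths: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    selective_centers: np.ndarray | None = field(repr=False, default=None)

    # -- decode ------------------------------------------------------------

    def cell_index(self, latent: np.ndarray) -> np.ndarray:
        return np.floor(np.asarray(latent, dtype=float) / self.cfg.quantization_step).astype(int)

    def identity_of(self, latent: np.ndarray) -> str:
        return "c" + "_".join(map(str, self.cell_index(latent)))

    def cell_center(self, latent: np.ndarray) -> np.ndarray:
        return (self.cell_index(latent) + 0.5) * self.cfg.quantization_step

    def is_invalid_identity(self, identity: str) -> bool:
        return _stable_hash_unit(identity, self.cfg.rng_seed) < self.cfg.invalid_fraction

    # -- energies ----------------------------------------------------------

    def noise_free_energies(self, z: np.ndarray) -> dict[str, float]:
        """Underlying per-pocket energy surfaces at an exact latent point."""
        z = np.asarray(z, dtype=float)
        out = {}
        for pocket in self.panel.all_ids:
            c, dep = self.centers[pocket], self.depths[pocket]
            sq = np.sum((z[None, :] - c) ** 2, axis=1)
            out[pocket] = float(
                self.cfg.baseline_energy
                + np.sum(dep * np.exp(-sq / (2.0 * self.cfg.well_width**2)))
            )
        return out

    def _noisy_energies(self, identity: str, center: np.ndarray) -> dict[str, float]:
        # noise is seeded per (identity, fidelity): a molecule re-docked at
        # the same effort reproduces its energies across processes
        salt = int.from_bytes(
            hashlib.sha256(
                f"{self.cfg.rng_seed}:{self.noise_sd}:{identity}".encode()
            ).digest()[:4],
            "big",
        )
        rng = np.random.default_rng(salt)
        clean = self.noise_free_energies(center)
        return {
            p: e + rng.normal(0.0, self.noise_sd) for p, e in clean.items()
        }

    # -- contract ----------------------------------------------------------

    def evaluate(self, latent: np.ndarray) -> OracleResult:
        latent = np.asarray(latent, dtype=float)
        if not np.all(np.isfinite(latent)):
            raise ValueError("latent coordinates must be finite")
        if latent.shape[-1] != self.cfg.dim:
            raise AdapterError(
                f"latent has {latent.shape[-1]} dims, landscape has {self.cfg.dim}"
            )
        identity = self.identity_of(latent)
        if self.is_invalid_identity(identity):
            return OracleResult(identity=identity, valid=False)
        energies = self._noisy_energies(identity, self.cell_center(latent))
        return OracleResult(identity=identity, valid=True, energies=EnergyProfile(energies))

    def high_fidelity(self) -> "SyntheticOracle":
        """Validation-effort twin: same landscape, lower docking noise."""
        return replace(self, noise_sd=self.cfg.validation_noise_sd)


def make_synthetic_oracle(
    cfg: SyntheticLandscapeConfig,
    panel: PocketPanel,
    score_config: ScoreConfig = ScoreConfig(),
) -> SyntheticOracle:
    """Build a reproducible synthetic landscape for a pocket panel.

    The target pocket receives ``n_selective_wells`` deep wells whose
    centers are kept at least ``3 * well_width`` away from every off-target
    well center, so selective optima exist by construction; its remaining
    wells and all off-target wells are placed from the latent prior
    (truncated to |z| <= 2 so random sampling reaches them).  Build-time
    assertions check that the noise-free score at each selective-well
    center is a hit and that far-from-well regions score below 0.2.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    dim = cfg.dim

    def draw_center() -> np.ndarray:
        return np.clip(rng.standard_normal(dim), -2.0, 2.0)

    selective = np.array([draw_center() for _ in range(cfg.n_selective_wells)])
    min_sep = 3.0 * cfg.well_width

    centers: dict[str, np.ndarray] = {}
    depths: dict[str, np.ndarray] = {}
    deep = cfg.well_depth_range[0]
    for pocket in panel.off_target_ids:
        pts = []
        while len(pts) < cfg.n_wells_per_pocket:
            c = draw_center()
            if np.min(np.linalg.norm(selective - c, axis=1)) >= min_sep:
                pts.append(c)
        centers[pocket] = np.array(pts)
        depths[pocket] = rng.uniform(*sorted(cfg.well_depth_range), size=cfg.n_wells_per_pocket)

    n_plain = max(cfg.n_wells_per_pocket - cfg.n_selective_wells, 0)
    plain = np.array([draw_center() for _ in range(n_plain)]).reshape(n_plain, dim)
    centers[panel.target_id] = np.vstack([selective, plain])
    depths[panel.target_id] = np.r_[
        np.full(cfg.n_selective_wells, deep),
        rng.uniform(*sorted(cfg.well_depth_range), size=n_plain),
    ]

    oracle = SyntheticOracle(
        cfg=cfg,
        panel=panel,
        noise_sd=cfg.noise_sd,
        centers=centers,
        depths=depths,
        selective_centers=selective,
    )

    for c in selective:
        s = boltzmann_score(
            EnergyProfile(oracle.noise_free_energies(c)), panel, score_config
        )
        if not s > score_config.hit_threshold:
            raise AssertionError(
                f"selective-well center scores {s:.3f} <= hit threshold; "
                "landscape construction violated"
            )
    far = np.full(dim, 8.0)  # all well centers lie within |z| <= 2
    s_far = boltzmann_score(
        EnergyProfile(oracle.noise_free_energies(far)), panel, score_config
    )
    if not s_far < 0.2:
        raise AssertionError(f"baseline region scores {s_far:.3f} >= 0.2")
    return oracle


def apply_invalid_rule(
    result: OracleResult,
    panel: PocketPanel,
    config: ScoreConfig,
    rule: str = "fixed",
) -> EnergyProfile:
    """Placeholder energies for an invalid decode.

    ``rule="fixed"``: every pocket gets ``config.invalid_energy``
    (-5.0 kcal/mol by default).  ``rule="anybind_plus_one"``: every pocket
    gets ``anybind_energy + 1``, the variant appropriate when the anybind
    calibration differs from the default panel.  Both produce a low,
    constant score that steers the optimizer away without poisoning the
    surrogate.
    """
    if result.valid:
        raise ValueError("invalid rule applied to a valid result")
    if rule == "fixed":
        e = config.invalid_energy
    elif rule == "anybind_plus_one":
        e = config.anybind_energy + 1.0
    else:
        raise ValueError(f"unknown invalid rule {rule!r}")
    return EnergyProfile({p: e for p in panel.all_ids})


def rescore(
    oracle_high_fidelity: Oracle,
    records: Sequence,
    panel: PocketPanel,
    config: ScoreConfig,
) -> list:
    """Re-evaluate records at validation effort and re-rank.

    Each record's latent point is re-run through the low-noise oracle, its
    score recomputed from the fresh energies, and the records returned
    sorted by the *rescored* score, descending.  All inputs must be valid
    decodes.
    """
    out = []
    for rec in records:
        if not rec.valid:
            raise ValueError(f"cannot rescore invalid record {rec.identity!r}")
        res = oracle_high_fidelity.evaluate(np.asarray(rec.latent, dtype=float))
        score = boltzmann_score(res.energies, panel, config)
        out.append(replace(rec, phase="rescore", energies=res.energies, score=score))
    out.sort(key=lambda r: r.score, reverse=True)
    return out


# ---------------------------------------------------------------------------
# Real-system adapter interfaces (documented contracts; no bundled weights
# or binaries — the test suite never invokes these).


class DecoderAdapter(Protocol):
    """Generative-decoder contract: latent vector -> canonical SMILES.

    ``decode`` returns ``(smiles, valid)``; ``valid=False`` signals that
    the decoded molecule could not be embedded in 3-D (and so cannot be
    docked).  Implementations should raise :class:`AdapterError` for
    infrastructure failures.
    """

    def decode(self, latent: np.ndarray) -> tuple[str, bool]: ...


class DockingAdapter(Protocol):
    """Docking-engine contract: molecule + receptor panel -> energies.

    ``dock`` returns best-pose binding energies in kcal/mol, one per
    pocket identifier.  Receptors are referenced by identifier (e.g. PDB
    id; the FLT3 target pocket derives from the gilteritinib complex,
    PDB 6JQR) and prepared as PDBQT files by the implementation.
    ``exhaustiveness`` is the engine's search-effort setting (8 during
    optimization, 64 for validation).
    """

    def dock(
        self, smiles: str, pocket_ids: Sequence[str], exhaustiveness: int = 8
    ) -> dict[str, float]: ...
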