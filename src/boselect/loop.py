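"""End-to-end run orchestration: random initialization, Bayesian
optimization, duplicate caching, hit summarization, and validation rescoring.

A run evaluates ``n_init`` latent-prior samples, then performs ``n_bo``
optimization iterations: refit the GP surrogate on every (hypercube point,
score) pair observed so far — *including* cached repeats, whose flat
repeated scores teach the GP appropriately long lengthscales — propose the
next point by seeded expected-improvement ascent, evaluate it through the
oracle, and append the record.  Duplicate molecule identities return their
previously computed energies and score; invalid decodes receive the fixed
placeholder energies.  Hit statistics count unique molecules only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import oracle as oracle_mod
from .acquisition import AcquisitionConfig, propose_candidate
from .gp import fit_gp
from .latent import EPS, from_hypercube, to_hypercube, sample_latent_prior
from .oracle import Oracle, apply_invalid_rule
from .scoring import EnergyProfile, PocketPanel, ScoreConfig, boltzmann_score

__all__ = [
    "MoleculeRecord",
    "RunConfig",
    "run_random_phase",
    "run_bo_phase",
    "summarize_hits",
    "hit_rate",
    "run_pipeline",
    "history_to_dataframe",
]

logger = logging.getLogger("boselect")


@dataclass(frozen=True)
class MoleculeRecord:
    """One evaluated candidate."""

    iteration: int
    phase: str  # random | bo | rescore
    latent: np.ndarray
    hypercube: np.ndarray
    identity: str
    valid: bool
    energies: EnergyProfile
    score: float
    cached: bool = False


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one optimization run."""

    panel: PocketPanel
    n_init: int = 150
    n_bo: int = 200
    dim: int = 56
    score_config: ScoreConfig = field(default_factory=ScoreConfig)
    acquisition_config: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    gp_noise_variance: float = 0.2
    gp_restarts: int = 4
    invalid_rule: str = "fixed"
    top_k: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_init < 2:
            raise ValueError("n_init must be >= 2")
        if self.n_bo < 0:
            raise ValueError("n_bo must be >= 0")


class _Cache:
    """Per-identity evaluation cache: the duplicate-proposal contract."""

    def __init__(self) -> None:
        self._store: dict[str, tuple[bool, EnergyProfile, float]] = {}

    def __contains__(self, identity: str) -> bool:
        return identity in self._store

    def get(self, identity: str) -> tuple[bool, EnergyProfile, float]:
        return self._store[identity]

    def put(self, identity: str, valid: bool, energies: EnergyProfile, score: float) -> None:
        self._store[identity] = (valid, energies, score)


def _evaluate_point(
    orc: Oracle,
    z: np.ndarray,
    u: np.ndarray,
    cache: _Cache,
    cfg: RunConfig,
    iteration: int,
    phase: str,
) -> MoleculeRecord:
    try:
        result = orc.evaluate(z)
    except oracle_mod.AdapterError as err:
        raise oracle_mod.AdapterError(
            f"oracle failure at {phase} iteration {iteration}: {err}"
        ) from err
    if result.identity in cache:
        valid, energies, score = cache.get(result.identity)
        cached = True
    else:
        cached = False
        valid = result.valid
        if valid:
            energies = result.energies
        else:
            energies = apply_invalid_rule(
                result, cfg.panel, cfg.score_config, rule=cfg.invalid_rule
            )
        score = boltzmann_score(energies, cfg.panel, cfg.score_config)
        cache.put(result.identity, valid, energies, score)
    return MoleculeRecord(
        iteration=iteration,
        phase=phase,
        latent=np.asarray(z, dtype=float),
        hypercube=np.asarray(u, dtype=float),
        identity=result.identity,
        valid=valid,
        energies=energies,
        score=score,
        cached=cached,
    )


def run_random_phase(
    orc: Oracle, cfg: RunConfig, cache: _Cache | None = None
) -> list[MoleculeRecord]:
    """Evaluate ``n_init`` latent-prior samples through the oracle."""
    cache = _Cache() if cache is None else cache
    init_seed, _ = _phase_seeds(cfg.rng_seed)
    Z = sample_latent_prior(cfg.n_init, cfg.dim, seed=init_seed)
    history: list[MoleculeRecord] = []
    best = -np.inf
    for i, z in enumerate(Z):
        rec = _evaluate_point(orc, z, to_hypercube(z), cache, cfg, i, "random")
        history.append(rec)
        best = max(best, rec.score)
        _log_record(rec, best)
    return history


def _phase_seeds(rng_seed: int) -> tuple[np.random.SeedSequence, np.random.SeedSequence]:
    init_ss, bo_ss = np.random.SeedSequence(rng_seed).spawn(2)
    return init_ss, bo_ss


def run_bo_phase(
    orc: Oracle,
    history: list[MoleculeRecord],
    cfg: RunConfig,
    cache: _Cache | None = None,
) -> list[MoleculeRecord]:
    """Append ``n_bo`` Bayesian-optimization iterations to a history.

    Every observed (hypercube, score) pair — cached repeats included —
    enters the GP training set; each proposed point therefore appears in
    the training data of the next iteration.  If a proposal lands within
    1e-9 of an existing training input three times in a row, the next
    proposal is replaced by a uniform random draw to avoid stalling.
    """
    if cache is None:
        cache = _Cache()
        for rec in history:
            if rec.identity not in cache:
                cache.put(rec.identity, rec.valid, rec.energies, rec.score)
    history = list(history)
    _, bo_ss = _phase_seeds(cfg.rng_seed)
    iter_seeds = bo_ss.spawn(cfg.n_bo)
    start_iter = max((r.iteration for r in history), default=-1) + 1
    stall_count = 0
    best = max((r.score for r in history), default=-np.inf)
    for j in range(cfg.n_bo):
        gp_ss, acq_ss, fallback_ss = iter_seeds[j].spawn(3)
        X = np.array([r.hypercube for r in history])
        y = np.array([r.score for r in history])
        model = fit_gp(
            X,
            y,
            noise_variance=cfg.gp_noise_variance,
            seed=np.random.default_rng(gp_ss),
            n_restarts=cfg.gp_restarts,
        )
        if stall_count >= 3:
            u = np.random.default_rng(fallback_ss).uniform(EPS, 1 - EPS, size=cfg.dim)
            stall_count = 0
        else:
            u = propose_candidate(
                model, history, cfg.acquisition_config, rng=np.random.default_rng(acq_ss)
            )
        if np.min(np.linalg.norm(X - u, axis=1)) < 1e-9:
            stall_count += 1
        else:
            stall_count = 0
        z = from_hypercube(u)
        rec = _evaluate_point(orc, z, u, cache, cfg, start_iter + j, "bo")
        history.append(rec)
        best = max(best, rec.score)
        _log_record(rec, best)
    return history


def _log_record(rec: MoleculeRecord, best: float) -> None:
    logger.info(
        "iter=%d phase=%s identity=%s valid=%s score=%.4f cached=%s best=%.4f",
        rec.iteration, rec.phase, rec.identity, rec.valid, rec.score, rec.cached, best,
    )


def summarize_hits(
    history: Sequence[MoleculeRecord], cfg: RunConfig
) -> pd.DataFrame:
    """Unique-molecule hit table, sorted by score descending.

    A hit is a unique identity whose score strictly exceeds the hit
    threshold; repeated proposals of one molecule count once.
    """
    seen: dict[str, MoleculeRecord] = {}
    for rec in history:
        seen.setdefault(rec.identity, rec)
    hits = [
        r for r in seen.values()
        if r.score > cfg.score_config.hit_threshold
    ]
    hits.sort(key=lambda r: r.score, reverse=True)
    return history_to_dataframe(hits, cfg.panel)


def hit_rate(history: Sequence[MoleculeRecord], cfg: RunConfig, phase: str) -> float:
    """Unique hits / unique identities among one phase's records."""
    recs = [r for r in history if r.phase == phase]
    seen: dict[str, float] = {}
    for r in recs:
        seen.setdefault(r.identity, r.score)
    if not seen:
        return float("nan")
    n_hits = sum(1 for s in seen.values() if s > cfg.score_config.hit_threshold)
    return n_hits / len(seen)


def history_to_dataframe(
    history: Sequence[MoleculeRecord], panel: PocketPanel
) -> pd.DataFrame:
    rows = []
    for r in history:
        row = {
            "iteration": r.iteration,
            "phase": r.phase,
            "identity": r.identity,
            "valid": r.valid,
            "cached": r.cached,
            "score": r.score,
        }
        for p in panel.all_ids:
            row[f"E_{p}"] = r.energies[p]
        row["latent"] = json.dumps(list(map(float, r.latent)))
        row["hypercube"] = json.dumps(list(map(float, r.hypercube)))
        rows.append(row)
    cols = (
        ["iteration", "phase", "identity", "valid", "cached", "score"]
        + [f"E_{p}" for p in panel.all_ids]
        + ["latent", "hypercube"]
    )
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(
    cfg: RunConfig,
    orc: Oracle,
    orc_high_fidelity: Oracle | None = None,
    outdir: str | Path | None = None,
) -> tuple[list[MoleculeRecord], pd.DataFrame, pd.DataFrame]:
    """Random phase -> BO phase -> validation rescore of hits -> top-k.

    Returns ``(history, hits, top_k)``.  With ``outdir`` set, writes
    ``history.csv``, ``hits.csv``, ``top_k.csv`` and ``run.log``; partial
    history is flushed to disk if a phase fails midway.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        logger.addHandler(handler)
    history: list[MoleculeRecord] = []
    try:
        cache = _Cache()
        history = run_random_phase(orc, cfg, cache)
        history = run_bo_phase(orc, history, cfg, cache)
    except Exception:
        if outdir is not None and history:
            history_to_dataframe(history, cfg.panel).to_csv(
                outdir / "history.csv", index=False
            )
        raise
    finally:
        if outdir is not None:
            logger.removeHandler(handler)
            handler.close()

    hits = summarize_hits(history, cfg)

    seen: dict[str, MoleculeRecord] = {}
    for rec in history:
        seen.setdefault(rec.identity, rec)
    hit_records = [
        r for r in seen.values()
        if r.valid and r.score > cfg.score_config.hit_threshold
    ]
    if orc_high_fidelity is not None and hit_records:
        rescored = oracle_mod.rescore(
            orc_high_fidelity, hit_records, cfg.panel, cfg.score_config
        )
    else:
        rescored = sorted(hit_records, key=lambda r: r.score, reverse=True)
    top = history_to_dataframe(rescored[: cfg.top_k], cfg.panel)

    if outdir is not None:
        history_to_dataframe(history, cfg.panel).to_csv(outdir / "history.csv", index=False)
        hits.to_csv(outdir / "hits.csv", index=False)
        top.to_csv(outdir / "top_k.csv", index=False)
    return history, hits, top
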