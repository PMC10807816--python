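"""Chemical-shift-driven ranking of candidate structural models.

Candidate structures (expert-built variants of a template: side-chain
flips, water placements, chromophore adjustments) are scored by how well
their predicted shifts reproduce an experimental shift table, or how well a
(green, blue) model pairing reproduces experimental shift *differences*.
Agreement is summarized as RMSD on the key intersection, with per-nucleus
breakdowns pooled after gyromagnetic scaling so ¹H/¹³C/¹⁵N residuals are
commensurate.  Ranking is ascending in the chosen score with lexicographic
id tie-breaks, which makes it deterministic and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import gyromagnetic_scale
from .fragmentation import FragmentationParams, fragment_all
from .shifts import (
    ShieldingEngine,
    ShiftDifferenceRecord,
    ShiftTable,
    assemble_shifts,
    delta_shifts,
)
from .structure import Structure

__all__ = [
    "CandidateModel",
    "AgreementScore",
    "score_model",
    "score_pairing",
    "rank_models",
    "rank_pairings",
]

AtomKey = tuple[int, str]


@dataclass
class CandidateModel:
    id: str
    structure: Structure
    provenance: str = ""


@dataclass
class AgreementScore:
    """Prediction-vs-experiment agreement summary (all RMSDs in ppm)."""

    rmsd_iso: float
    n_sites: int
    rmsd_csa: float | None = None
    per_nucleus: dict[str, float] = field(default_factory=dict)
    pooled_rmsd: float = np.nan  # gyromagnetically scaled iso (+CSA) pooling
    sign_agreement: float | None = None


def _rmsd(residuals: Sequence[float]) -> float:
    arr = np.asarray(residuals, dtype=float)
    return float(np.sqrt(np.mean(arr**2)))


def _predict(m: CandidateModel, engine: ShieldingEngine, params: FragmentationParams) -> ShiftTable:
    return assemble_shifts(fragment_all(m.structure, params), engine)


def score_model(
    m: CandidateModel,
    experimental: ShiftTable,
    engine: ShieldingEngine,
    params: FragmentationParams = FragmentationParams(),
    site_filter: Iterable[AtomKey] | None = None,
) -> AgreementScore:
    """Score one candidate against an experimental shift table.

    Residuals are taken on the key intersection only, so sites present in
    just one table never influence the score.  An empty intersection is a
    hard error.
    """
    predicted = _predict(m, engine, params)
    keys = set(predicted.keys()) & set(experimental.keys())
    if site_filter is not None:
        keys &= set(site_filter)
    keys = sorted(keys)
    if not keys:
        raise ValueError("no shared sites between prediction and experiment")

    iso_res: list[float] = []
    pooled: list[float] = []
    csa_res: list[float] = []
    by_nucleus: dict[str, list[float]] = {}
    for key in keys:
        p, e = predicted[key], experimental[key]
        r = p.iso - e.iso
        iso_res.append(r)
        scale = gyromagnetic_scale(e.nucleus)
        pooled.append(r * scale)
        by_nucleus.setdefault(e.nucleus, []).append(r)
        if p.csa is not None and e.csa is not None:
            comp = np.array(p.csa.as_tuple()) - np.array(e.csa.as_tuple())
            csa_res.extend(comp.tolist())
            pooled.extend((comp * scale).tolist())
    return AgreementScore(
        rmsd_iso=_rmsd(iso_res),
        n_sites=len(keys),
        rmsd_csa=_rmsd(csa_res) if csa_res else None,
        per_nucleus={nuc: _rmsd(v) for nuc, v in sorted(by_nucleus.items())},
        pooled_rmsd=_rmsd(pooled),
    )


def score_pairing(
    green: CandidateModel,
    blue: CandidateModel,
    experimental_delta: Sequence[ShiftDifferenceRecord],
    engine: ShieldingEngine,
    params: FragmentationParams = FragmentationParams(),
) -> AgreementScore:
    """Score a (green, blue) model pairing against experimental Δδ records.

    Predicted Δδ = assembled(blue) − assembled(green).  Reports RMSD and the
    sign-agreement fraction; the latter is None when no site has a non-zero
    predicted and experimental difference (sign undefined).
    """
    if not experimental_delta:
        raise ValueError("experimental delta records are empty")
    pred = delta_shifts(_predict(green, engine, params), _predict(blue, engine, params))
    pred_by_key = {r.key: r for r in pred}
    residuals: list[float] = []
    pooled: list[float] = []
    by_nucleus: dict[str, list[float]] = {}
    signs_total = 0
    signs_match = 0
    for rec in experimental_delta:
        p = pred_by_key.get(rec.key)
        if p is None:
            continue
        r = p.delta_iso - rec.delta_iso
        residuals.append(r)
        scale = gyromagnetic_scale(rec.nucleus)
        pooled.append(r * scale)
        by_nucleus.setdefault(rec.nucleus, []).append(r)
        if p.delta_iso != 0.0 and rec.delta_iso != 0.0:
            signs_total += 1
            if np.sign(p.delta_iso) == np.sign(rec.delta_iso):
                signs_match += 1
    if not residuals:
        raise ValueError("no shared sites between predicted and experimental deltas")
    return AgreementScore(
        rmsd_iso=_rmsd(residuals),
        n_sites=len(residuals),
        per_nucleus={nuc: _rmsd(v) for nuc, v in sorted(by_nucleus.items())},
        pooled_rmsd=_rmsd(pooled),
        sign_agreement=signs_match / signs_total if signs_total else None,
    )


def _metric(score: AgreementScore, key: str) -> float:
    if key == "iso":
        return score.rmsd_iso
    if key == "combined":
        return score.pooled_rmsd
    raise ValueError(f"unknown ranking key {key!r} (use 'iso' or 'combined')")


def rank_models(
    candidates: Sequence[CandidateModel],
    experimental: ShiftTable,
    engine: ShieldingEngine,
    params: FragmentationParams = FragmentationParams(),
    key: str = "iso",
    site_filter: Iterable[AtomKey] | None = None,
) -> pd.DataFrame:
    """Rank candidates ascending by score; ties break on id.

    Returns the full score table with a 1-based ``rank`` column.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    ids = [c.id for c in candidates]
    if len(set(ids)) != len(ids):
        raise ValueError("candidate ids must be unique")
    rows = []
    for c in candidates:
        s = score_model(c, experimental, engine, params, site_filter)
        rows.append(
            {
                "id": c.id,
                "score": _metric(s, key),
                "rmsd_iso": s.rmsd_iso,
                "rmsd_csa": s.rmsd_csa,
                "pooled_rmsd": s.pooled_rmsd,
                "n_sites": s.n_sites,
            }
        )
    df = pd.DataFrame(rows).sort_values(["score", "id"]).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def rank_pairings(
    pairings: Sequence[tuple[str, CandidateModel, CandidateModel]],
    experimental_delta: Sequence[ShiftDifferenceRecord],
    engine: ShieldingEngine,
    params: FragmentationParams = FragmentationParams(),
) -> pd.DataFrame:
    """Rank (green, blue) pairings by Δδ RMSD, ascending; ties break on id."""
    if not pairings:
        raise ValueError("need at least one pairing")
    rows = []
    for pid, g, b in pairings:
        s = score_pairing(g, b, experimental_delta, engine, params)
        rows.append(
            {
                "id": pid,
                "score": s.rmsd_iso,
                "sign_agreement": s.sign_agreement,
                "n_sites": s.n_sites,
            }
        )
    df = pd.DataFrame(rows).sort_values(["score", "id"]).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
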