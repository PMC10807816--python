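"""Sequence-family analysis for the green/blue color switch.

Works on an aligned protein family (the alignment itself is an input, never
computed here).  Sequences are classified green/blue by the diagnostic
residue at a reference position (Leu → green, Gln → blue at position 105 in
the green reference numbering).  Per-position statistics follow:

* the cross-group conservation scatter — for each group, the modal residue's
  within-group frequency against that same residue type's frequency in the
  other group (fully conserved columns land at (1, 1); a perfect diagnostic
  column at (1, 0));
* a Shannon-entropy conservation score, reported as log₂20 − H bits;
* mutual information between columns with the average-product correction
  (APC), a light-weight covariation detector;
* gyromagnetic scaling of shift differences so ¹⁵N and ¹³C perturbations
  share a frequency scale, and a rank-correlation of |Δδ| against
  conservation with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from .constants import MAX_COLUMN_ENTROPY_BITS, gyromagnetic_scale
from .shifts import ShiftDifferenceRecord

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "MSA",
    "read_alignment_fasta",
    "classify_by_diagnostic",
    "conservation_scatter",
    "entropy_conservation",
    "CovariationMatrix",
    "mi_apc",
    "scale_delta",
    "CorrelationResult",
    "correlate_shift_conservation",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
DEFAULT_DIAGNOSTIC_RULE = {"L": "green", "Q": "blue"}


@dataclass
class MSA:
    """Aligned sequences with a reference for position numbering.

    ``column_map`` maps 1-based reference residue numbers to 0-based
    alignment columns (columns where the reference has a gap are unmapped).
    """

    ids: list[str]
    sequences: list[str]
    ref_id: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("one id per sequence required")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must have equal length")
        if self.ref_id not in self.ids:
            raise ValueError(f"ref_id {self.ref_id!r} not among sequence ids")
        self.sequences = [s.upper() for s in self.sequences]
        ref = self.sequences[self.ids.index(self.ref_id)]
        cmap: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(ref):
            if ch != GAP:
                pos += 1
                cmap[pos] = col
        self.column_map: dict[int, int] = cmap

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def mapped_positions(self) -> list[int]:
        return sorted(self.column_map)

    def column(self, col: int) -> np.ndarray:
        return np.array([s[col] for s in self.sequences])

    def column_at_position(self, position: int) -> np.ndarray:
        try:
            col = self.column_map[position]
        except KeyError:
            raise KeyError(
                f"reference position {position} is not mapped to an alignment column"
            ) from None
        return self.column(col)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.ids, self.sequences):
                fh.write(f">{sid}\n{seq}\n")


def read_alignment_fasta(path: str | Path, ref_id: str | None = None) -> MSA:
    """Read an aligned FASTA; the reference defaults to the first record."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    ids = [r.id for r in records]
    return MSA(
        ids=ids,
        sequences=[str(r.seq) for r in records],
        ref_id=ref_id if ref_id is not None else ids[0],
    )


# ---------------------------------------------------------------------------
# classification and conservation


def classify_by_diagnostic(
    msa: MSA,
    ref_position: int = 105,
    rule: Mapping[str, str] = DEFAULT_DIAGNOSTIC_RULE,
) -> dict[str, str]:
    """Label each sequence by its residue at the diagnostic position.

    Residues outside the rule, and gaps, are labelled ``unclassified``.
    """
    column = msa.column_at_position(ref_position)
    return {
        sid: rule.get(ch, "unclassified") for sid, ch in zip(msa.ids, column)
    }


def _group_rows(msa: MSA, labels: Mapping[str, str], group: str) -> list[int]:
    return [i for i, sid in enumerate(msa.ids) if labels.get(sid) == group]


def _column_freqs(
    chars: np.ndarray, gap_policy: str = "ignore", pseudocount: float = 0.0
) -> tuple[dict[str, float], int]:
    """Residue-type frequencies of one column slice; returns (freqs, n_counted)."""
    if gap_policy == "ignore":
        chars = chars[chars != GAP]
        alphabet = AMINO_ACIDS
    elif gap_policy == "state":
        alphabet = AMINO_ACIDS + GAP
    else:
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    n = chars.size
    counts = {a: pseudocount for a in alphabet}
    for ch in chars:
        counts[ch] = counts.get(ch, pseudocount) + 1.0
    total = sum(counts.values())
    if total <= 0:
        return {}, 0
    return {a: c / total for a, c in counts.items()}, n


def conservation_scatter(
    msa: MSA, labels: Mapping[str, str], gap_policy: str = "ignore"
) -> pd.DataFrame:
    """Cross-group conservation profile per mapped reference position.

    For each position: the modal residue within each group, its within-group
    frequency, and that residue type's frequency in the *other* group.
    Modal-residue ties break alphabetically.
    """
    rows_g = _group_rows(msa, labels, "green")
    rows_b = _group_rows(msa, labels, "blue")
    if not rows_g or not rows_b:
        raise ValueError("both green and blue groups must be nonempty")
    out = []
    for pos in msa.mapped_positions():
        chars = msa.column(msa.column_map[pos])
        fg, ng = _column_freqs(chars[rows_g], gap_policy)
        fb, nb = _column_freqs(chars[rows_b], gap_policy)
        rec: dict[str, object] = {"position": pos}
        if ng and fg:
            top_g = min(fg, key=lambda a: (-fg[a], a))
            rec.update(
                top_residue_green=top_g,
                p_green=fg[top_g],
                p_same_in_blue=fb.get(top_g, 0.0) if nb else np.nan,
            )
        else:
            rec.update(top_residue_green=None, p_green=np.nan, p_same_in_blue=np.nan)
        if nb and fb:
            top_b = min(fb, key=lambda a: (-fb[a], a))
            rec.update(
                top_residue_blue=top_b,
                p_blue=fb[top_b],
                p_same_in_green=fg.get(top_b, 0.0) if ng else np.nan,
            )
        else:
            rec.update(top_residue_blue=None, p_blue=np.nan, p_same_in_green=np.nan)
        out.append(rec)
    return pd.DataFrame(out).set_index("position")


def entropy_conservation(
    msa: MSA, gap_policy: str = "ignore", pseudocount: float = 0.0
) -> pd.DataFrame:
    """Shannon entropy per mapped column and conservation = log₂20 − H (bits).

    All-gap columns (under the ignore policy) are reported as missing.
    """
    if msa.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    rows = []
    for pos in msa.mapped_positions():
        chars = msa.column(msa.column_map[pos])
        freqs, n = _column_freqs(chars, gap_policy, pseudocount)
        if n == 0 and pseudocount == 0:
            rows.append({"position": pos, "entropy": np.nan, "conservation": np.nan})
            continue
        p = np.array([v for v in freqs.values() if v > 0])
        h = float(-(p * np.log2(p)).sum())
        rows.append(
            {
                "position": pos,
                "entropy": h,
                "conservation": MAX_COLUMN_ENTROPY_BITS - h,
            }
        )
    return pd.DataFrame(rows).set_index("position")


# ---------------------------------------------------------------------------
# covariation (MI + APC)


@dataclass
class CovariationMatrix:
    """Pairwise column mutual information (bits) and its APC correction."""

    positions: list[int]
    mi: np.ndarray
    apc: np.ndarray

    def top_pairs(self, corrected: bool = True, k: int = 10) -> pd.DataFrame:
        m = self.apc if corrected else self.mi
        n = len(self.positions)
        rows = [
            {
                "pos_i": self.positions[i],
                "pos_j": self.positions[j],
                "mi": self.mi[i, j],
                "apc_mi": self.apc[i, j],
            }
            for i in range(n)
            for j in range(i + 1, n)
        ]
        df = pd.DataFrame(rows)
        return df.sort_values("apc_mi" if corrected else "mi", ascending=False).head(k)


def _encode_columns(msa: MSA, gap_policy: str) -> np.ndarray:
    """Integer-encode mapped columns; gap = -1 under the ignore policy."""
    alphabet = AMINO_ACIDS + (GAP if gap_policy == "state" else "")
    lut = {ch: i for i, ch in enumerate(alphabet)}
    cols = []
    for pos in msa.mapped_positions():
        chars = msa.column(msa.column_map[pos])
        cols.append(np.array([lut.get(ch, -1) for ch in chars], dtype=np.int64))
    return np.vstack(cols)  # (n_positions, n_sequences)


def _pair_mi(a: np.ndarray, b: np.ndarray, n_states: int, pseudocount: float) -> float:
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    if a.size == 0:
        return 0.0
    joint = np.bincount(a * n_states + b, minlength=n_states * n_states).astype(float)
    joint = joint.reshape(n_states, n_states) + pseudocount
    total = joint.sum()
    if total <= 0:
        return 0.0
    pxy = joint / total
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    mi = float(np.sum(pxy[nz] * np.log2(pxy[nz] / np.outer(px, py)[nz])))
    return max(mi, 0.0)


def mi_apc(
    msa: MSA, gap_policy: str = "ignore", pseudocount: float = 0.0
) -> CovariationMatrix:
    """Pairwise MI in bits with the average-product correction subtracted.

    APCᵢⱼ = MIᵢⱼ − MI̅ᵢ·MI̅ⱼ / MI̅, with row means taken over off-diagonal
    entries.  Constant columns yield MI 0 by convention; the correction
    preserves symmetry.
    """
    positions = msa.mapped_positions()
    if len(positions) < 2:
        raise ValueError("need at least 2 mapped columns")
    enc = _encode_columns(msa, gap_policy)
    n_states = len(AMINO_ACIDS) + (1 if gap_policy == "state" else 0)
    n = len(positions)
    mi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mi[i, j] = mi[j, i] = _pair_mi(enc[i], enc[j], n_states, pseudocount)
    if n > 1:
        row_mean = mi.sum(axis=1) / (n - 1)
        overall = mi[np.triu_indices(n, 1)].mean()
    else:  # pragma: no cover - guarded above
        row_mean, overall = np.zeros(n), 0.0
    apc = mi.copy()
    if overall > 0:
        corr = np.outer(row_mean, row_mean) / overall
        apc = mi - corr
    np.fill_diagonal(apc, 0.0)
    np.fill_diagonal(mi, 0.0)
    return CovariationMatrix(positions=positions, mi=mi, apc=apc)


# ---------------------------------------------------------------------------
# shift-difference vs conservation


def scale_delta(
    record: "ShiftDifferenceRecord | tuple[str, float]",
    reference_nucleus: str = "13C",
) -> float:
    """Δδ × |γ(nucleus)|/|γ(reference)|; identity on the reference nucleus.

    Accepts a :class:`ShiftDifferenceRecord` or a ``(nucleus, delta)`` pair.
    """
    if isinstance(record, ShiftDifferenceRecord):
        nucleus, value = record.nucleus, record.delta_iso
    else:
        nucleus, value = record
    return value * gyromagnetic_scale(nucleus, reference_nucleus)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n_sites: int
    n_permutations: int
    alternative: str


def _as_position_series(values) -> pd.Series:
    if isinstance(values, pd.DataFrame):
        if "conservation" not in values.columns:
            raise ValueError("profile DataFrame needs a 'conservation' column")
        return values["conservation"]
    if isinstance(values, pd.Series):
        return values
    return pd.Series(dict(values))


def correlate_shift_conservation(
    deltas: Mapping[int, float] | pd.Series,
    conservation: "Mapping[int, float] | pd.Series | pd.DataFrame",
    n_permutations: int = 10_000,
    seed: int = 0,
    alternative: str = "greater",
) -> CorrelationResult:
    """Spearman correlation of |Δδ| (gyromagnetically scaled) vs conservation.

    The p-value comes from seeded label permutations using the unbiased
    (1 + exceedances) / (1 + permutations) estimator; ``alternative`` is
    ``greater`` (larger perturbations at more conserved sites, the default),
    ``less`` or ``two-sided``.
    """
    d = _as_position_series(deltas).abs()
    c = _as_position_series(conservation)
    shared = sorted(set(d.index) & set(c.index))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 matched positions, got {len(shared)}")
    x = stats.rankdata(c.loc[shared].to_numpy(dtype=float))
    y = stats.rankdata(d.loc[shared].to_numpy(dtype=float))
    n = len(shared)

    def corr(yy: np.ndarray) -> np.ndarray:
        xc = x - x.mean()
        yc = yy - yy.mean(axis=-1, keepdims=True)
        denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=-1))
        return (yc @ xc) / denom

    rho = float(corr(y[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(y) for _ in range(n_permutations)])
    rho_null = corr(perms)
    if alternative == "greater":
        exceed = np.sum(rho_null >= rho)
    elif alternative == "less":
        exceed = np.sum(rho_null <= rho)
    elif alternative == "two-sided":
        exceed = np.sum(np.abs(rho_null) >= abs(rho))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1.0 + float(exceed)) / (1.0 + n_permutations)
    return CorrelationResult(
        rho=rho, p_value=p, n_sites=n, n_permutations=n_permutations,
        alternative=alternative,
    )
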