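"""Seeded end-to-end validation studies over the synthetic generators.

Each function runs one self-contained simulation study — fragmentation
against an exhaustive scan, closed-form electrostatics checks, planted-truth
model ranking, covariation recovery, permutation-test calibration and power
— and returns plain numbers.  The analysis drivers and the acceptance script
are thin wrappers over these.

Problem sizes are desk scale by design: structures of 10–40 residues,
families of a few hundred sequences, 100 seeded repetitions per study.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .constants import COULOMB_CONSTANT, gyromagnetic_scale
from .conservation import (
    classify_by_diagnostic,
    conservation_scatter,
    correlate_shift_conservation,
    entropy_conservation,
    mi_apc,
)
from .electrostatics import PointChargeSet, field_at, potential_at, potential_grid
from .fragmentation import FragmentationParams, build_buffer, fragment_all
from .scoring import CandidateModel, rank_models
from .shifts import MockShieldingEngine, assemble_shifts, delta_shifts, whole_system_shifts
from .structure import Structure
from .synthetic import SyntheticSpec, make_msa, make_shift_pair, make_structure, perturb_structure

__all__ = [
    "fragmentation_oracle_study",
    "electrostatics_checks",
    "model_recovery_study",
    "conservation_checks",
    "covariation_recovery_study",
    "permutation_calibration_study",
    "correlation_power_study",
    "gyromagnetic_checks",
]


def _child_seeds(seed: int, tag: int, n: int) -> np.ndarray:
    """n reproducible sub-seeds below 2³¹ derived from (seed, tag)."""
    ss = np.random.SeedSequence([int(seed), tag])
    return ss.generate_state(n) % (2**31)


# ---------------------------------------------------------------------------
# fragmentation vs exhaustive oracle


def fragmentation_oracle_study(
    seed: int = 0,
    n_structures: int = 100,
    size_range: tuple[int, int] = (10, 40),
    locality_radius: float = 3.0,
) -> dict[str, float]:
    """Accelerated buffers vs exhaustive scans, and assembly vs whole-system.

    For each seeded structure, every residue serves as a core; the KD-tree
    buffer must equal the exhaustive O(N²) scan, and the shift table
    assembled from per-fragment mock-engine runs must match a single
    whole-system evaluation.
    """
    params = FragmentationParams()
    engine = MockShieldingEngine(locality_radius)
    seeds = _child_seeds(seed, 101, n_structures)
    n_buffers = 0
    n_buffer_agree = 0
    max_err = 0.0
    for k, s_seed in enumerate(seeds):
        rng = np.random.default_rng(int(s_seed))
        n_res = int(rng.integers(size_range[0], size_range[1] + 1))
        spec = SyntheticSpec(
            seed=int(s_seed), n_residues=n_res, with_ligand=bool(k % 2)
        )
        s = make_structure(spec)
        for core in (r.index for r in s.residues):
            fast = build_buffer(s, core, params)
            slow = build_buffer(s, core, params, method="exhaustive")
            n_buffers += 1
            n_buffer_agree += fast == slow
        assembled = assemble_shifts(
            fragment_all(s, params, include_ligands=True), engine
        )
        whole = whole_system_shifts(s, engine)
        for key in assembled.keys():
            err = abs(assembled[key].iso - whole[key].iso)
            err = max(
                err,
                max(
                    abs(a - w)
                    for a, w in zip(
                        assembled[key].csa.as_tuple(), whole[key].csa.as_tuple()
                    )
                ),
            )
            max_err = max(max_err, err)
    return {
        "n_structures": n_structures,
        "buffer_agreement_fraction": n_buffer_agree / n_buffers,
        "n_buffers_checked": n_buffers,
        "max_assembly_error_ppm": max_err,
    }


# ---------------------------------------------------------------------------
# electrostatics closed forms


def electrostatics_checks(seed: int = 0) -> dict[str, float]:
    """Closed-form Coulomb checks, numerical E = −∇V, and exact linearity."""
    # single unit charge at the Coulomb distance → exactly 1 V
    cs = PointChargeSet(np.zeros((1, 3)), np.array([1.0]), ["q"])
    v = potential_at([COULOMB_CONSTANT, 0.0, 0.0], cs)
    coulomb_rel_err = abs(v - 1.0)
    f = field_at([10.0, 0.0, 0.0], cs)
    coulomb_rel_err = max(
        coulomb_rel_err, abs(f.magnitude - COULOMB_CONSTANT) / COULOMB_CONSTANT
    )

    # E = −∇V by central differences at 0.05 Å spacing
    rng = np.random.default_rng(_child_seeds(seed, 102, 1)[0])
    pocket = PointChargeSet(
        rng.uniform(-4, 4, (25, 3)), rng.uniform(-1, 1, 25), [f"q{i}" for i in range(25)]
    )
    grad_rel_err = 0.0
    h = 0.05
    for point in rng.uniform(6, 9, (5, 3)):
        vals, _ = potential_grid(pocket, (point - h, point + h), h, mask_radius=0.0)
        grad = np.array(
            [
                (vals[2, 1, 1] - vals[0, 1, 1]) / (2 * h),
                (vals[1, 2, 1] - vals[1, 0, 1]) / (2 * h),
                (vals[1, 1, 2] - vals[1, 1, 0]) / (2 * h),
            ]
        )
        e = field_at(point, pocket).field / 100.0  # back to V/Å
        grad_rel_err = max(
            grad_rel_err, float(np.max(np.abs(e + grad)) / np.max(np.abs(e)))
        )

    # superposition and linearity, exact
    doubled = PointChargeSet(pocket.coords, 2.0 * pocket.charges, pocket.labels)
    p0 = np.array([7.0, 7.0, 7.0])
    superposition_exact = float(
        potential_at(p0, doubled) == 2.0 * potential_at(p0, pocket)
        and np.array_equal(field_at(p0, doubled).field, 2.0 * field_at(p0, pocket).field)
    )
    return {
        "coulomb_max_rel_error": coulomb_rel_err,
        "gradient_max_rel_error": grad_rel_err,
        "linearity_exact": superposition_exact,
    }


# ---------------------------------------------------------------------------
# planted-truth model recovery


def model_recovery_study(
    seed: int = 0,
    n_reps: int = 100,
    n_candidates: int = 5,
    n_residues: int = 15,
    noise_sigma: float = 0.2,
    decoy_jitter: float = 0.3,
) -> dict[str, float]:
    """How often the generating model ranks first among jittered decoys.

    The experimental table is the truth model's assembled mock shifts plus
    Gaussian noise (σ in ppm); decoys perturb every coordinate by
    ``decoy_jitter`` Å.
    """
    engine = MockShieldingEngine(3.0)
    params = FragmentationParams()
    seeds = _child_seeds(seed, 103, n_reps)
    wins = 0
    for s_seed in seeds:
        spec = SyntheticSpec(seed=int(s_seed), n_residues=n_residues)
        truth = make_structure(spec)
        rng = np.random.default_rng(int(s_seed) + 1)
        candidates = [CandidateModel("candidate_0_truth", truth)] + [
            CandidateModel(
                f"candidate_{k}_decoy", perturb_structure(truth, decoy_jitter, rng)
            )
            for k in range(1, n_candidates)
        ]
        experimental = assemble_shifts(fragment_all(truth, params), engine)
        for key in experimental.keys():
            experimental[key].iso += rng.normal(0.0, noise_sigma)
            experimental[key].csa = None
        ranking = rank_models(candidates, experimental, engine, params, key="iso")
        wins += ranking.iloc[0]["id"] == "candidate_0_truth"
    return {
        "n_reps": n_reps,
        "recovery_fraction": wins / n_reps,
        "noise_sigma_ppm": noise_sigma,
    }


# ---------------------------------------------------------------------------
# conservation statistics


def conservation_checks(seed: int = 0) -> dict[str, float]:
    """Deterministic family-statistics checks on one planted alignment."""
    spec = SyntheticSpec(
        seed=int(_child_seeds(seed, 104, 1)[0]),
        n_sequences=300,
        alignment_length=60,
        diagnostic_position=30,
        conservation_levels=np.concatenate([np.ones(5), np.full(55, 0.6)]),
    )
    msa, truth_labels, _ = make_msa(spec)
    predicted = classify_by_diagnostic(msa, ref_position=30)
    classification_accuracy = float(
        np.mean([predicted[sid] == truth_labels[sid] for sid in msa.ids])
    )
    profile = conservation_scatter(msa, predicted)
    conserved = profile.loc[1]
    diagnostic = profile.loc[30]

    # MI of two identical uniform 4-state columns is exactly 2 bits
    from .conservation import MSA

    rows = [c * 2 for c in "ACDE" * 25]
    mi_two_bits = mi_apc(
        MSA(ids=[f"s{i}" for i in range(len(rows))], sequences=rows, ref_id="s0")
    ).mi[0, 1]
    return {
        "classification_accuracy": classification_accuracy,
        "conserved_point": (float(conserved.p_green), float(conserved.p_same_in_blue)),
        "diagnostic_point": (float(diagnostic.p_green), float(diagnostic.p_same_in_blue)),
        "mi_identical_uniform4_bits": float(mi_two_bits),
    }


def covariation_recovery_study(
    seed: int = 0,
    n_seeds: int = 100,
    n_sequences: int = 500,
    n_columns: int = 50,
    planted_pair: tuple[int, int] = (10, 35),
    coupling: float = 1.0,
) -> dict[str, float]:
    """How often the planted covarying pair tops the APC-corrected MI ranking."""
    seeds = _child_seeds(seed, 105, n_seeds)
    hits = 0
    for s_seed in seeds:
        spec = SyntheticSpec(
            seed=int(s_seed),
            n_sequences=n_sequences,
            alignment_length=n_columns,
            diagnostic_position=1,
            covarying_pairs=[(*planted_pair, coupling)],
        )
        msa, _, _ = make_msa(spec)
        cov = mi_apc(msa)
        top = cov.top_pairs(corrected=True, k=1).iloc[0]
        hits += {int(top.pos_i), int(top.pos_j)} == set(planted_pair)
    return {"n_seeds": n_seeds, "top_rank_fraction": hits / n_seeds}


# ---------------------------------------------------------------------------
# correlation pipeline calibration and power


def _correlation_rejection(
    s_seed: int,
    structure: Structure,
    conservation_bits: dict[int, float],
    effect_slope: float,
    n_permutations: int,
    alpha: float,
) -> bool:
    spec = SyntheticSpec(
        seed=int(s_seed), n_residues=len(conservation_bits), effect_slope=effect_slope
    )
    green, blue, _ = make_shift_pair(structure, spec, conservation_bits)
    records = delta_shifts(green, blue)
    from .conservation import scale_delta

    scaled = {r.key[0]: scale_delta(r) for r in records if r.key[1] == "CA"}
    result = correlate_shift_conservation(
        scaled, conservation_bits, n_permutations=n_permutations, seed=int(s_seed)
    )
    return result.p_value < alpha


def _conservation_from_planted_msa(s_seed: int, n_sites: int) -> dict[int, float]:
    mspec = SyntheticSpec(
        seed=int(s_seed),
        n_sequences=200,
        alignment_length=n_sites,
        diagnostic_position=max(1, n_sites // 2),
    )
    msa, _, _ = make_msa(mspec)
    bits = entropy_conservation(msa)["conservation"]
    return {int(pos): float(v) for pos, v in bits.items()}


def permutation_calibration_study(
    seed: int = 0,
    n_seeds: int = 100,
    n_sites: int = 40,
    n_permutations: int = 10_000,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Type-I error of the permutation test under the null (no effect)."""
    seeds = _child_seeds(seed, 106, n_seeds)
    structure = make_structure(SyntheticSpec(seed=int(seeds[0]), n_residues=n_sites))
    rejections = 0
    for s_seed in seeds:
        cons = _conservation_from_planted_msa(int(s_seed), n_sites)
        rejections += _correlation_rejection(
            int(s_seed), structure, cons, 0.0, n_permutations, alpha
        )
    return {"n_seeds": n_seeds, "type_i_rate": rejections / n_seeds, "alpha": alpha}


def correlation_power_study(
    seed: int = 0,
    n_seeds: int = 100,
    n_sites: int = 40,
    effect_slope: float = 0.5,
    n_permutations: int = 10_000,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Power of the pipeline under the conservation-dependent effect model.

    Effect magnitude is ``effect_slope`` ppm per bit of conservation with
    σ = 0.2 ppm Gaussian noise at 40 sites (the study conditions).
    """
    seeds = _child_seeds(seed, 107, n_seeds)
    structure = make_structure(SyntheticSpec(seed=int(seeds[0]), n_residues=n_sites))
    rejections = 0
    for s_seed in seeds:
        cons = _conservation_from_planted_msa(int(s_seed), n_sites)
        rejections += _correlation_rejection(
            int(s_seed), structure, cons, effect_slope, n_permutations, alpha
        )
    return {"n_seeds": n_seeds, "power": rejections / n_seeds, "alpha": alpha}


def gyromagnetic_checks() -> dict[str, float]:
    """The ¹⁵N→¹³C-equivalent scaling factor from the tabulated constants."""
    return {
        "n15_to_c13_factor": gyromagnetic_scale("15N", "13C"),
        "c13_identity": gyromagnetic_scale("13C", "13C"),
    }
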