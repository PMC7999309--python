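"""Synthetic abundance matrices and interaction networks with known truth.

The generator emulates a small label-free LC-MS proteomics study: a couple of
thousand proteins quantified across two small groups of urine-exosome samples
(cases vs. controls), log-normal abundances spanning several orders of
magnitude, a planted subset of differential proteins with a fixed log2 effect,
and optionally missing (not-quantified) entries.  A companion network
generator plants cytokine-to-case-protein enrichment into a STRING-style
scored edge list.  Every downstream stage of the pipeline can therefore be
tested against a known ground truth without any external download.

Abundance model (log2 scale)::

    log2 a_ij = base + b_i + s_i * g_j + eps_ij

where ``b_i ~ Normal(0, protein_sd)`` is a per-protein baseline offset,
``g_j`` indicates case membership, ``s_i`` is the signed planted effect
(zero for non-differential proteins), and ``eps_ij ~ Normal(0, noise_sd)``
is measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "GroundTruth", "generate_abundance", "generate_network"]

MISSING_MODES = ("random", "intensity_dependent")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design the package targets: 5 case vs. 7
    control samples, ~2000 proteins, log-normal abundances with a planted
    5% differential fraction at |log2FC| = 2.
    """

    n_proteins: int = 2000
    n_case: int = 5
    n_control: int = 7
    frac_diff: float = 0.05
    effect_log2fc: float = 2.0
    base_log2_mean: float = 20.0
    protein_sd: float = 2.0
    noise_sd: float = 0.5
    missing_rate: float = 0.1
    missing_mode: str = "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or int(self.n_proteins) != self.n_proteins:
            raise ValueError("n_proteins must be a positive integer")
        for name in ("n_case", "n_control"):
            v = getattr(self, name)
            if int(v) != v or v < 2:
                raise ValueError(f"{name} must be an integer >= 2")
        if not 0.0 <= self.frac_diff <= 1.0:
            raise ValueError("frac_diff must lie in [0, 1]")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        if self.protein_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("protein_sd and noise_sd must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.missing_mode not in MISSING_MODES:
            raise ValueError(f"missing_mode must be one of {MISSING_MODES}")

    @property
    def n_differential(self) -> int:
        return int(round(self.frac_diff * self.n_proteins))


@dataclass
class GroundTruth:
    """What was planted: signed log2 effects and cytokine classes."""

    differential_proteins: dict[str, float] = field(default_factory=dict)
    planted_cytokines: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "differential_proteins": dict(self.differential_proteins),
            "planted_cytokines": dict(self.planted_cytokines),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            differential_proteins={str(k): float(v) for k, v in d.get("differential_proteins", {}).items()},
            planted_cytokines={str(k): str(v) for k, v in d.get("planted_cytokines", {}).items()},
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_mnar_probs(log2_abund: np.ndarray, target_rate: float, scale: float = 1.0) -> np.ndarray:
    """Per-cell missing probabilities, logistic in log2 abundance.

    Lower-intensity cells are more likely to drop out.  The logistic midpoint
    is chosen by bisection so the marginal missing probability equals
    ``target_rate``.
    """
    if target_rate == 0.0:
        return np.zeros_like(log2_abund)
    lo, hi = log2_abund.min() - 60.0, log2_abund.max() + 60.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        rate = _sigmoid((mid - log2_abund) / scale).mean()
        if rate > target_rate:
            hi = mid
        else:
            lo = mid
    return _sigmoid((0.5 * (lo + hi) - log2_abund) / scale)


def generate_abundance(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate an abundance matrix with planted differential proteins.

    Returns
    -------
    (matrix, metadata, truth)
        ``matrix`` is proteins x samples with NaN for missing entries;
        ``metadata`` maps sample_id to group ("case" / "control");
        ``truth`` records the planted signed log2 effects.
    """
    n, n_case, n_ctrl = config.n_proteins, config.n_case, config.n_control
    m = n_case + n_ctrl
    width = max(4, len(str(n)))
    proteins = [f"P{i + 1:0{width}d}" for i in range(n)]
    samples = [f"case_{j + 1}" for j in range(n_case)] + [f"ctrl_{j + 1}" for j in range(n_ctrl)]
    group = np.array([1] * n_case + [0] * n_ctrl)

    ss = np.random.SeedSequence(config.seed)
    rng_effect, rng_base, rng_noise, rng_miss = (np.random.default_rng(c) for c in ss.spawn(4))

    # Planted effects: half up-shifted in cases, half down; an odd count
    # favors the up direction.
    n_diff = config.n_differential
    effects = np.zeros(n)
    diff_idx = np.sort(rng_effect.choice(n, size=n_diff, replace=False))
    n_up = (n_diff + 1) // 2
    up_idx = diff_idx[:n_up]
    down_idx = diff_idx[n_up:]
    effects[up_idx] = config.effect_log2fc
    effects[down_idx] = -config.effect_log2fc

    baseline = rng_base.normal(0.0, config.protein_sd, size=n)
    noise = rng_noise.normal(0.0, config.noise_sd, size=(n, m))
    log2_abund = config.base_log2_mean + baseline[:, None] + effects[:, None] * group[None, :] + noise
    values = np.exp2(log2_abund)

    if config.missing_rate > 0:
        if config.missing_mode == "random":
            probs = np.full((n, m), config.missing_rate)
        else:
            probs = _calibrate_mnar_probs(log2_abund, config.missing_rate)
        mask = rng_miss.random((n, m)) < probs
        # Every protein and sample must keep at least one quantified value;
        # when a full row/column drops out, restore its brightest cell.
        for i in np.flatnonzero(mask.all(axis=1)):
            mask[i, np.argmax(log2_abund[i])] = False
        for j in np.flatnonzero(mask.all(axis=0)):
            mask[np.argmax(log2_abund[:, j]), j] = False
        values = np.where(mask, np.nan, values)

    matrix = pd.DataFrame(values, index=pd.Index(proteins, name="protein_id"), columns=samples)
    metadata = pd.DataFrame(
        {"group": ["case"] * n_case + ["control"] * n_ctrl},
        index=pd.Index(samples, name="sample_id"),
    )
    truth = GroundTruth(
        differential_proteins={proteins[i]: float(effects[i]) for i in diff_idx},
    )
    return matrix, metadata, truth


def generate_network(
    proteins: list[str],
    case_proteins: set[str] | frozenset[str],
    cytokine_panel: list[str],
    planted_cytokines: set[str] | frozenset[str],
    p_base: float = 0.05,
    p_planted: float = 0.8,
    score_range: tuple[float, float] = (0.15, 0.999),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a scored cytokine-protein edge list with planted enrichment.

    Each (cytokine, protein) pair receives an edge independently: with
    probability ``p_planted`` when the cytokine is planted and the protein is
    case-associated, and ``p_base`` otherwise.  Scores are uniform over
    ``score_range`` (a STRING-like combined-confidence interval).

    Returns the edge list as a DataFrame with columns
    (node1, node2, combined_score); node1 is always the cytokine.
    """
    if not 0.0 <= p_base <= 1.0 or not 0.0 <= p_planted <= 1.0:
        raise ValueError("p_base and p_planted must lie in [0, 1]")
    lo, hi = score_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("score_range must be an interval within [0, 1]")
    unknown = set(planted_cytokines) - set(cytokine_panel)
    if unknown:
        raise ValueError(f"planted cytokines not in panel: {sorted(unknown)}")
    unknown = set(case_proteins) - set(proteins)
    if unknown:
        raise ValueError(f"case proteins not in protein list: {sorted(unknown)}")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    is_case = np.array([p in case_proteins for p in proteins])
    planted = set(planted_cytokines)

    rows: list[tuple[str, str, float]] = []
    for cyt in cytokine_panel:
        probs = np.where(is_case & (cyt in planted), p_planted, p_base)
        hit = rng.random(len(proteins)) < probs
        scores = lo + (hi - lo) * rng.random(len(proteins))
        for j in np.flatnonzero(hit):
            rows.append((cyt, proteins[j], round(float(scores[j]), 6)))
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])
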