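"""Synthetic benchmark generator with planted synergy motifs.

Every input the pipeline consumes can be generated here: a compound
library whose binary structure fingerprints determine latent
target-inhibition probabilities, imbalanced per-target bioactivity
screens (IC50 in μM or an inactive flag), a small panel of cell lines
with 0/1/2 mutation codes, and a drug-pair synergy table whose signal
comes from planted multi-target "synergy motifs" plus Gaussian noise.

Because the generative law is known, downstream stages — profile
estimation, the synergy regressor, and the input-space interpretation —
can be scored by how well they recover the planted motifs, which is the
package's substitute for public dose–response databases.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TARGET_NAMES",
    "Requirement",
    "SynergyMotif",
    "LatentProfileModel",
    "CompoundLibrary",
    "ActivityRecord",
    "CellLinePanel",
    "AblationMode",
    "simulate_compound_library",
    "simulate_bioactivity_screen",
    "simulate_cell_lines",
    "true_synergy",
    "simulate_synergy_table",
    "make_ablation_profiles",
    "default_motifs",
]

#: The 13-protein panel used at default geometry: frequent targets of
#: small-molecule inhibitors in breast-cancer combination screens
#: (mostly receptor tyrosine kinases, plus TOP2A/TUBB1/MCL1/NR1I2).
DEFAULT_TARGET_NAMES = (
    "ABL1", "CSF1R", "EGFR", "FLT1", "FLT4", "KDR", "KIT",
    "MCL1", "NR1I2", "PDGFRB", "RET", "TOP2A", "TUBB1",
)

#: Activity threshold: compounds with IC50 at or below this (μM) count
#: as inhibitory.
ACTIVE_IC50_UM = 10.0


def target_names(n_targets: int) -> tuple[str, ...]:
    """Canonical target names: the 13-protein panel, or generic labels."""
    if n_targets == len(DEFAULT_TARGET_NAMES):
        return DEFAULT_TARGET_NAMES
    return tuple(f"T{i:02d}" for i in range(n_targets))


class Requirement(enum.Enum):
    """How a motif target must be inhibited: by at least one drug, or both."""

    ONE = "one"
    BOTH = "both"


@dataclass(frozen=True)
class SynergyMotif:
    """A planted target-combination rule that confers synergy.

    A drug pair *covers* the motif on a line when every target with
    requirement ONE is inhibited (profile >= threshold) by at least one
    drug and every BOTH target by both drugs; a covered pair gains
    ``effect_size * line_weights[line]`` synergy.
    """

    requirements: dict[int, Requirement]
    effect_size: float
    line_weights: tuple[float, ...]
    inhibition_threshold: float = 0.5

    def __post_init__(self):
        if len(self.requirements) < 2:
            raise ValueError("a motif needs at least 2 targets")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if not 0.0 < self.inhibition_threshold < 1.0:
            raise ValueError("inhibition_threshold must be in (0, 1)")
        if any(w < 0 for w in self.line_weights):
            raise ValueError("line_weights must be non-negative")

    def covered(self, profile_a: np.ndarray, profile_b: np.ndarray) -> bool:
        th = self.inhibition_threshold
        for t, req in self.requirements.items():
            a, b = profile_a[t], profile_b[t]
            if req is Requirement.ONE:
                if max(a, b) < th:
                    return False
            else:
                if min(a, b) < th:
                    return False
        return True

    def to_dict(self) -> dict:
        return {
            "requirements": {str(t): r.value for t, r in self.requirements.items()},
            "effect_size": self.effect_size,
            "line_weights": list(self.line_weights),
            "inhibition_threshold": self.inhibition_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynergyMotif":
        return cls(
            requirements={int(t): Requirement(v) for t, v in d["requirements"].items()},
            effect_size=float(d["effect_size"]),
            line_weights=tuple(float(w) for w in d["line_weights"]),
            inhibition_threshold=float(d.get("inhibition_threshold", 0.5)),
        )


@dataclass(frozen=True)
class LatentProfileModel:
    """Sparse logistic map from fingerprint bits to inhibition probability.

    latent[t] = logistic(W[t] @ fingerprint + b[t]).  Weight sparsity makes
    each target depend on a small subset of bits, so structurally similar
    compounds get similar profiles — the coupling the random-weight
    ablation relies on.
    """

    weights: np.ndarray  # (T, B)
    biases: np.ndarray  # (T,)

    def profiles(self, fingerprints: np.ndarray) -> np.ndarray:
        logits = fingerprints.astype(float) @ self.weights.T + self.biases
        return 1.0 / (1.0 + np.exp(-logits))


@dataclass
class CompoundLibrary:
    """A set of compounds with fingerprints and latent inhibition profiles."""

    compound_ids: list[str]
    fingerprints: np.ndarray  # (n, B) of 0/1
    latent_inhibition: np.ndarray  # (n, T) in [0, 1]
    profile_model: LatentProfileModel

    def __post_init__(self):
        assert set(np.unique(self.fingerprints)).issubset({0, 1}) or self.n_compounds == 0
        if self.n_compounds:
            assert self.latent_inhibition.min() >= 0.0
            assert self.latent_inhibition.max() <= 1.0

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_targets(self) -> int:
        return self.latent_inhibition.shape[1]

    @property
    def n_bits(self) -> int:
        return self.fingerprints.shape[1]

    def latent_profile_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.latent_inhibition.copy(),
            index=pd.Index(self.compound_ids, name="compound_id"),
            columns=list(target_names(self.n_targets)),
        )


@dataclass(frozen=True)
class ActivityRecord:
    """One bioactivity measurement: an IC50 (μM) or an inactive flag."""

    compound_id: str
    target_index: int
    ic50_um: float | None = None
    inactive_flag: bool = False

    def __post_init__(self):
        if (self.ic50_um is None) == (not self.inactive_flag):
            raise ValueError("exactly one of ic50_um / inactive_flag must be set")
        if self.ic50_um is not None and self.ic50_um <= 0:
            raise ValueError("ic50_um must be positive")


@dataclass
class CellLinePanel:
    """Cell lines with per-gene mutation codes: 0 none, 1 loss-, 2 gain-of-function."""

    line_ids: list[str]
    mutation_codes: np.ndarray  # (L, G) over {0,1,2}

    def __post_init__(self):
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line_ids must be unique")
        if not set(np.unique(self.mutation_codes)).issubset({0, 1, 2}):
            raise ValueError("mutation codes must be in {0,1,2}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_genes(self) -> int:
        return self.mutation_codes.shape[1]

    def codes_for(self, line_id: str) -> np.ndarray:
        return self.mutation_codes[self.line_ids.index(line_id)]


class AblationMode(enum.Enum):
    """Feature-set variants for the four-way profile comparison."""

    TRUE_PROFILE = "true_profile"
    RANDOM_WEIGHT = "random_weight"
    SHUFFLED = "shuffled"
    FINGERPRINT = "fingerprint"


# --------------------------------------------------------------------- #
# generators
# --------------------------------------------------------------------- #

def simulate_compound_library(
    n_compounds: int = 98,
    n_bits: int = 256,
    n_targets: int = 13,
    sparsity: float = 0.2,
    seed: int = 0,
    profile_model: LatentProfileModel | None = None,
    weight_sparsity: float = 0.1,
    logit_scale: float = 5.0,
    activity_rate: float = 0.4,
) -> CompoundLibrary:
    """Simulate compounds with Bernoulli fingerprints and latent profiles.

    Fingerprint bits are i.i.d. Bernoulli(``sparsity``).  Latent inhibition
    probabilities come from a sparse logistic map of the bits (see
    :class:`LatentProfileModel`); pass ``profile_model`` to reuse the map of
    an existing library so two libraries share the same structure→profile
    law (e.g. a large screening library and the drug set to be profiled).

    ``activity_rate`` sets the fraction of compounds whose latent
    inhibition exceeds 0.5 for each target (calibrated per target).
    Inhibition profiles are sparse-ish in reality: a multi-target kinase
    inhibitor hits roughly 5-6 proteins of a 13-member frequent-target
    panel, so the default keeps per-target activity a minority property
    while leaving multi-target coverage common enough to learn from.
    """
    if n_compounds < 0:
        raise ValueError("n_compounds must be >= 0")
    if n_bits < 8:
        raise ValueError("n_bits must be >= 8")
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if not 0.0 < sparsity < 1.0:
        raise ValueError("sparsity must be in (0, 1)")

    rng = np.random.default_rng(seed)
    fingerprints = (rng.random((n_compounds, n_bits)) < sparsity).astype(np.int8)

    if profile_model is None:
        if not 0.0 < activity_rate < 1.0:
            raise ValueError("activity_rate must be in (0, 1)")
        k = max(1, round(weight_sparsity * n_bits))
        # scale weights so the logit sd is ~logit_scale, spreading latents
        # over (0, 1) rather than piling at 0.5
        sigma = logit_scale / math.sqrt(max(sparsity * (1 - sparsity) * k, 1e-12))
        weights = np.zeros((n_targets, n_bits))
        for t in range(n_targets):
            support = rng.choice(n_bits, size=k, replace=False)
            weights[t, support] = rng.normal(0.0, sigma, size=k)
        # calibrate each target's bias so that a fraction activity_rate of
        # the library inhibits it (latent >= 0.5).  This mirrors how such
        # target panels are assembled — targets are picked relative to the
        # drug set so each has a substantial inhibitor count, not a
        # free-floating one.  Small/empty libraries calibrate against a
        # reference fingerprint population instead.
        if n_compounds >= 64:
            cal = fingerprints.astype(np.float64)
        else:
            cal_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCA1]))
            cal = (cal_rng.random((4096, n_bits)) < sparsity).astype(np.float64)
        raw = cal @ weights.T  # (n_cal, T)
        biases = -np.quantile(raw, 1.0 - activity_rate, axis=0)
        profile_model = LatentProfileModel(weights=weights, biases=biases)
    else:
        if profile_model.weights.shape[1] != n_bits:
            raise ValueError("profile_model bit width does not match n_bits")
        if profile_model.weights.shape[0] != n_targets:
            raise ValueError("profile_model target count does not match n_targets")

    latent = (
        profile_model.profiles(fingerprints)
        if n_compounds
        else np.zeros((0, n_targets))
    )
    ids = [f"CPD-{i:05d}" for i in range(n_compounds)]
    return CompoundLibrary(ids, fingerprints, latent, profile_model)


def simulate_bioactivity_screen(
    library: CompoundLibrary,
    target_index: int,
    active_fraction: float = 0.1,
    label_noise: float = 0.0,
    seed: int = 0,
) -> list[ActivityRecord]:
    """Simulate one per-target screen with a controlled class imbalance.

    Compounds whose latent inhibition for the target is at or above the
    empirical ``(1 - active_fraction)``-quantile are labelled active and
    given an IC50 drawn log-uniformly on [0.01, 10] μM; the rest get the
    inactive flag.  ``label_noise`` swaps that fraction of the active set
    with randomly chosen inactives, corrupting labels while keeping the
    achieved class imbalance exactly at ``active_fraction``.
    """
    if not 0.0 < active_fraction < 1.0:
        raise ValueError("active_fraction must be in (0, 1)")
    if not 0.0 <= label_noise < 0.5:
        raise ValueError("label_noise must be in [0, 0.5)")
    if not 0 <= target_index < library.n_targets:
        raise IndexError(f"target_index {target_index} out of range [0, {library.n_targets})")

    n = library.n_compounds
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    latent = library.latent_inhibition[:, target_index]
    threshold = np.quantile(latent, 1.0 - active_fraction)
    active = latent >= threshold

    act_idx = np.flatnonzero(active)
    inact_idx = np.flatnonzero(~active)
    n_swap = min(int(round(label_noise * len(act_idx))), len(inact_idx))
    if n_swap > 0:
        out = rng.choice(act_idx, size=n_swap, replace=False)
        inn = rng.choice(inact_idx, size=n_swap, replace=False)
        active[out] = False
        active[inn] = True

    log_lo, log_hi = np.log(0.01), np.log(ACTIVE_IC50_UM)
    records = []
    for i in range(n):
        if active[i]:
            ic50 = float(np.exp(rng.uniform(log_lo, log_hi)))
            records.append(ActivityRecord(library.compound_ids[i], target_index, ic50_um=ic50))
        else:
            records.append(
                ActivityRecord(library.compound_ids[i], target_index, inactive_flag=True)
            )
    return records


def simulate_cell_lines(n_lines: int = 5, n_genes: int = 7, seed: int = 0) -> CellLinePanel:
    """Sample a panel of cell lines with uniform mutation codes in {0,1,2}."""
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 3, size=(n_lines, n_genes))
    ids = [f"LINE-{i}" for i in range(n_lines)]
    return CellLinePanel(ids, codes)


def true_synergy(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    line_index: int,
    motifs: list[SynergyMotif],
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """The planted generative law for a pair's synergy score on a line.

    score = sum over motifs of ``effect_size * line_weight * covered`` plus
    Normal(0, noise_sd^2) noise.  Positive scores mean synergy, zero means
    additivity; with only positive-effect motifs and no noise the score is
    never negative.
    """
    profile_a = np.asarray(profile_a, dtype=float)
    profile_b = np.asarray(profile_b, dtype=float)
    score = 0.0
    for m in motifs:
        if m.covered(profile_a, profile_b):
            score += m.effect_size * m.line_weights[line_index]
    if noise_sd > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        score += rng.normal(0.0, noise_sd)
    return float(score)


def simulate_synergy_table(
    library: CompoundLibrary,
    panel: CellLinePanel,
    motifs: list[SynergyMotif],
    n_pairs_per_line: int,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample unordered drug pairs per line and score them with the planted law.

    Returns a DataFrame with columns drug_a, drug_b, cell_line, zip_score;
    each unordered pair appears at most once per line, with drug_a < drug_b
    in library order.
    """
    n = library.n_compounds
    if n < 2:
        raise ValueError("library needs at least 2 compounds")
    for m in motifs:
        if len(m.line_weights) != panel.n_lines:
            raise ValueError("motif line_weights length must equal the number of cell lines")
    all_pairs = list(itertools.combinations(range(n), 2))
    if n_pairs_per_line > len(all_pairs):
        raise ValueError(
            f"n_pairs_per_line={n_pairs_per_line} exceeds the {len(all_pairs)} distinct pairs"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for li, line in enumerate(panel.line_ids):
        chosen = rng.choice(len(all_pairs), size=n_pairs_per_line, replace=False)
        for ci in chosen:
            i, j = all_pairs[ci]
            score = true_synergy(
                library.latent_inhibition[i],
                library.latent_inhibition[j],
                li,
                motifs,
                noise_sd=noise_sd,
                rng=rng,
            )
            rows.append(
                (library.compound_ids[i], library.compound_ids[j], line, score)
            )
    return pd.DataFrame(rows, columns=["drug_a", "drug_b", "cell_line", "zip_score"])


def make_ablation_profiles(
    library: CompoundLibrary,
    mode: AblationMode | str,
    seed: int = 0,
    estimated_profiles: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-drug feature tables for the four-way profile comparison.

    TRUE_PROFILE: the stage-1 estimated profiles when supplied, else the
    latent ones.  RANDOM_WEIGHT: profiles from a freshly drawn sparse
    logistic map — wrong targets, but structurally similar drugs still get
    similar profiles.  SHUFFLED: a seed-fixed derangement of the TRUE
    assignment, destroying the structure→profile link.  FINGERPRINT: the
    raw fingerprint bits.
    """
    mode = AblationMode(mode)
    if mode is AblationMode.FINGERPRINT:
        return pd.DataFrame(
            library.fingerprints.astype(float),
            index=pd.Index(library.compound_ids, name="compound_id"),
            columns=[f"bit_{i}" for i in range(library.n_bits)],
        )

    base = (
        estimated_profiles.loc[library.compound_ids]
        if estimated_profiles is not None
        else library.latent_profile_frame()
    )
    if mode is AblationMode.TRUE_PROFILE:
        return base.copy()
    rng = np.random.default_rng(seed)
    if mode is AblationMode.RANDOM_WEIGHT:
        fresh = simulate_compound_library(
            n_compounds=0,
            n_bits=library.n_bits,
            n_targets=library.n_targets,
            sparsity=0.2,
            seed=int(rng.integers(2**31)),
        ).profile_model
        vals = fresh.profiles(library.fingerprints)
        return pd.DataFrame(vals, index=base.index, columns=base.columns)
    # SHUFFLED: derangement so every drug gets another drug's profile
    perm = _derangement(library.n_compounds, rng)
    return pd.DataFrame(base.to_numpy()[perm], index=base.index, columns=base.columns)


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    if n < 2:
        raise ValueError("a derangement needs at least 2 items")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def default_motifs(n_lines: int = 5) -> list[SynergyMotif]:
    """Two planted motifs dominating different cell lines.

    Motif 1 (ONE/ONE/BOTH over targets 0,1,2) dominates the first lines;
    motif 2 (ONE/BOTH over targets 3,4) dominates the later ones — so the
    interpretation stage must recover different patterns per line, the way
    distinct synergy groups appear in different tumour subtypes.
    """
    w1 = np.full(n_lines, 0.2)
    w2 = np.full(n_lines, 0.2)
    w1[: max(1, n_lines // 2)] = 1.0
    w2[max(1, n_lines // 2):] = 1.0
    return [
        SynergyMotif(
            requirements={0: Requirement.ONE, 1: Requirement.ONE, 2: Requirement.BOTH},
            effect_size=5.0,
            line_weights=tuple(w1),
        ),
        SynergyMotif(
            requirements={3: Requirement.ONE, 4: Requirement.BOTH},
            effect_size=5.0,
            line_weights=tuple(w2),
        ),
    ]
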