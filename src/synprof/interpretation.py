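"""Input-space interpretation of the trained synergy ensemble.

The trained networks are probed with systematically generated binary
inhibition profiles: every 26-bit vector with exactly N ones (N ranging
over, e.g., 2..4) is concatenated with a cell line's mutation codes and
scored by averaging the swap-averaged predictions of the ensemble
members.  Each probe is then summarized per target as 0 (neither drug
inhibits), 1 (exactly one drug), or 2 (both drugs) — the ternary
"none/one/both" encoding — the top-k patterns are selected, and the
patterns are clustered agglomeratively on Euclidean distance.  On
synthetic data the discovered patterns are scored against the planted
motifs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage, to_tree

from .model import SynergyRegressor, predict_symmetric_matrix
from .synthetic import Requirement, SynergyMotif, target_names

__all__ = [
    "GeneratedProfile",
    "TernaryPattern",
    "PatternDendrogram",
    "RecoveryReport",
    "enumerate_binary_profiles",
    "score_generated_profiles",
    "ternary_summary",
    "select_top_patterns",
    "cluster_patterns",
    "motif_recovery_score",
    "discover_patterns",
]


@dataclass
class GeneratedProfile:
    """One binary 2T-bit probe with its ensemble-averaged predicted score."""

    bits: np.ndarray
    n_active: int
    cell_line: str
    predicted_score: float


@dataclass(frozen=True)
class TernaryPattern:
    """Per-target none/one/both summary of a probe, with its score."""

    states: tuple[int, ...]
    predicted_score: float
    cell_line: str = ""

    @property
    def n_active(self) -> int:
        return int(sum(self.states))


def enumerate_binary_profiles(n_columns: int = 26, n_active_range=range(2, 5)):
    """Yield every binary vector of length ``n_columns`` with exactly N ones.

    N runs over ``n_active_range``; within each N, combinations are
    produced in lexicographic order of the active positions (the order of
    ``itertools.combinations``).  Streaming: nothing is materialized.
    """
    n_active_values = list(n_active_range)
    if not n_active_values:
        raise ValueError("n_active_range must be non-empty")
    for n_active in n_active_values:
        if not 1 <= n_active <= n_columns:
            raise ValueError(f"N={n_active} outside [1, {n_columns}]")
    for n_active in n_active_values:
        for positions in itertools.combinations(range(n_columns), n_active):
            bits = np.zeros(n_columns, dtype=np.int8)
            bits[list(positions)] = 1
            yield bits


def score_generated_profiles(
    ensemble: list[SynergyRegressor],
    profiles,
    mutation_codes: np.ndarray,
    cell_line: str = "",
    chunk_size: int = 8192,
) -> list[GeneratedProfile]:
    """Score probes with the ensemble: mean over models of the swap-averaged
    prediction on (bits ++ mutation codes).

    Accepts any iterable of bit vectors and processes it in chunks.
    """
    if not ensemble:
        raise ValueError("ensemble must be non-empty")
    widths = {m.input_width for m in ensemble}
    if len(widths) != 1:
        raise ValueError(f"ensemble models disagree on input width: {sorted(widths)}")
    mutation_codes = np.asarray(mutation_codes, dtype=float)
    out: list[GeneratedProfile] = []
    it = iter(profiles)
    while True:
        chunk = list(itertools.islice(it, chunk_size))
        if not chunk:
            break
        bits = np.asarray(chunk, dtype=float)
        expected = ensemble[0].input_width
        if bits.shape[1] + mutation_codes.size != expected:
            raise ValueError(
                f"probe width {bits.shape[1]} + {mutation_codes.size} mutation codes "
                f"!= model input width {expected}"
            )
        X = np.hstack([bits, np.tile(mutation_codes, (len(chunk), 1))])
        scores = np.mean(
            [predict_symmetric_matrix(m, X) for m in ensemble], axis=0
        )
        for b, s in zip(chunk, scores):
            b = np.asarray(b, dtype=np.int8)
            out.append(
                GeneratedProfile(
                    bits=b,
                    n_active=int(b.sum()),
                    cell_line=cell_line,
                    predicted_score=float(s),
                )
            )
    return out


def ternary_summary(bits: np.ndarray) -> np.ndarray:
    """Collapse a 2T-bit probe to T states: bits[t] + bits[T+t] in {0,1,2}."""
    bits = np.asarray(bits)
    if bits.ndim != 1 or bits.size % 2:
        raise ValueError(f"expected an even-length 1-d bit vector, got shape {bits.shape}")
    T = bits.size // 2
    return (bits[:T] + bits[T:]).astype(np.int8)


def select_top_patterns(
    scored: list[GeneratedProfile], k: int = 20, dedup: bool = True
) -> list[TernaryPattern]:
    """Rank probes by predicted score and return the top-k ternary patterns.

    With ``dedup`` (default) probes collapsing to the same ternary pattern
    — in particular drug-slot mirror images — are merged keeping the
    maximum score, so the top-k lists distinct patterns.  Sorting is by
    score descending with lexicographic pattern order breaking ties.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    items: list[TernaryPattern] = []
    if dedup:
        best: dict[tuple[int, ...], TernaryPattern] = {}
        for p in scored:
            states = tuple(int(s) for s in ternary_summary(p.bits))
            cur = best.get(states)
            if cur is None or p.predicted_score > cur.predicted_score:
                best[states] = TernaryPattern(states, p.predicted_score, p.cell_line)
        items = list(best.values())
    else:
        items = [
            TernaryPattern(
                tuple(int(s) for s in ternary_summary(p.bits)), p.predicted_score, p.cell_line
            )
            for p in scored
        ]
    if len(items) < k:
        warnings.warn(f"only {len(items)} candidates for top-{k}", stacklevel=2)
    items.sort(key=lambda t: (-t.predicted_score, t.states))
    return items[:k]


@dataclass
class PatternDendrogram:
    """Agglomerative clustering result over ternary patterns."""

    merges: np.ndarray  # scipy linkage matrix (n-1, 4)
    labels: list[str]
    patterns: list[TernaryPattern] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["child_a", "child_b", "height", "size"]
        ).astype({"child_a": int, "child_b": int, "size": int})

    def flat_clusters(self, height: float) -> np.ndarray:
        return fcluster(self.merges, t=height, criterion="distance")

    def to_newick(self) -> str:
        """Newick string with pattern ids as leaf labels and branch lengths
        derived from merge heights."""
        tree = to_tree(self.merges)

        def walk(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return walk(tree, tree.dist) + ";"


def cluster_patterns(
    patterns: list[TernaryPattern], metric: str = "euclidean", method: str = "average"
) -> PatternDendrogram:
    """Cluster ternary state vectors agglomeratively (Euclidean, average
    linkage by default).  Duplicate patterns merge first at height 0."""
    if len(patterns) < 2:
        raise ValueError("need at least 2 patterns to cluster")
    states = np.asarray([p.states for p in patterns], dtype=float)
    Z = scipy_linkage(states, method=method, metric=metric)
    labels = [f"P{i:02d}" for i in range(len(patterns))]
    return PatternDendrogram(merges=Z, labels=labels, patterns=list(patterns))


@dataclass
class RecoveryReport:
    """How well the top patterns recover each planted motif."""

    per_motif: list[dict]

    def to_dict(self) -> dict:
        return {"per_motif": self.per_motif}

    @property
    def match_scores(self) -> list[float]:
        return [m["match_score"] for m in self.per_motif]


def _pattern_satisfies(states: tuple[int, ...], motif: SynergyMotif) -> float:
    satisfied = 0
    for t, req in motif.requirements.items():
        s = states[t] if t < len(states) else 0
        if req is Requirement.ONE and s >= 1:
            satisfied += 1
        elif req is Requirement.BOTH and s == 2:
            satisfied += 1
    return satisfied / len(motif.requirements)


def motif_recovery_score(
    patterns: list[TernaryPattern], motifs: list[SynergyMotif]
) -> RecoveryReport:
    """Score each planted motif against a ranked top-pattern list.

    match score = max over patterns of (satisfied requirements / total);
    a state >= 1 satisfies a ONE requirement, state == 2 satisfies BOTH.
    The rank (1-based) of the best-matching pattern is reported.
    """
    per_motif = []
    for mi, motif in enumerate(motifs):
        if not patterns:
            warnings.warn("empty pattern list; recovery scores are 0", stacklevel=2)
            per_motif.append(
                {"motif": mi, "match_score": 0.0, "best_rank": None, "best_pattern": None}
            )
            continue
        scores = [_pattern_satisfies(p.states, motif) for p in patterns]
        best_i = int(np.argmax(scores))
        per_motif.append(
            {
                "motif": mi,
                "match_score": float(scores[best_i]),
                "best_rank": best_i + 1,
                "best_pattern": list(patterns[best_i].states),
            }
        )
    return RecoveryReport(per_motif=per_motif)


def discover_patterns(
    ensemble: list[SynergyRegressor],
    mutation_codes: np.ndarray,
    cell_line: str = "",
    n_targets: int = 13,
    n_active_range=range(2, 5),
    k: int = 20,
    dedup: bool = True,
    linkage_method: str = "average",
) -> tuple[list[TernaryPattern], PatternDendrogram]:
    """End-to-end interpretation for one cell line.

    Enumerate probes, score them with the ensemble, take the top-k ternary
    patterns, and cluster them.  Returns (patterns, dendrogram).
    """
    probes = enumerate_binary_profiles(2 * n_targets, n_active_range)
    scored = score_generated_profiles(ensemble, probes, mutation_codes, cell_line)
    top = select_top_patterns(scored, k=k, dedup=dedup)
    dendro = cluster_patterns(top, method=linkage_method) if len(top) >= 2 else None
    return top, dendro


def patterns_frame(patterns: list[TernaryPattern], n_targets: int | None = None) -> pd.DataFrame:
    """Tabulate patterns: one row per pattern, one state column per target."""
    if not patterns:
        return pd.DataFrame()
    T = n_targets or len(patterns[0].states)
    names = target_names(T)
    rows = []
    for i, p in enumerate(patterns):
        row = {"pattern_id": f"P{i:02d}"}
        row.update({name: int(s) for name, s in zip(names, p.states)})
        row["n_active"] = p.n_active
        row["predicted_score"] = p.predicted_score
        row["cell_line"] = p.cell_line
        rows.append(row)
    return pd.DataFrame(rows)
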