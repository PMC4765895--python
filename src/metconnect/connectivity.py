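"""Signed Kolmogorov-Smirnov connectivity scoring of disease signatures
against drug-induced gene rank profiles.

Each rank profile is one drug-treatment instance: a permutation of the gene
universe, with rank 1 the most drug-up-regulated gene (the orientation is a
fixed convention; flip the ranks with :func:`reverse_profile` for the opposite
reading).  For a gene set occupying sorted positions ``V(1..t)`` among ``n``
ranks the signed enrichment statistic is::

    a = max_j [ j/t - V(j)/n ]        (concentration toward the top)
    b = max_j [ V(j)/n - (j-1)/t ]    (concentration toward the bottom)
    ks = a if a > b else -b

The connectivity score of an (up, down) signature is ``ks_up - ks_down`` when
the two statistics differ in sign (or either is zero) and 0 otherwise; a
negative score means the disease-up genes sit among the drug-down ranks and
vice versa, i.e. the drug reverses the disease signature.  Significance is
assessed by a permutation null (random gene sets of matching sizes) with a
one-sided alternative for negative connectivity, followed by BH adjustment
across all instances of a screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import DiseaseSignature, bh_fdr

__all__ = [
    "RankProfile",
    "ConnectivityResult",
    "ks_statistic",
    "connectivity_score",
    "connectivity_pvalue",
    "screen_instances",
    "reverse_profile",
    "results_to_frame",
    "write_rank_profiles",
    "read_rank_profiles",
    "write_screen_results",
    "read_screen_results",
]


@dataclass
class RankProfile:
    """One drug-treatment instance: a rank permutation over the gene universe.

    ``ranks[i]`` is the rank (1..n) of ``genes[i]``; the ranks must form an
    exact permutation of ``1..n``.
    """

    instance_id: str
    drug_id: str
    cell_line: str
    genes: tuple[str, ...]
    ranks: np.ndarray

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.ranks = np.asarray(self.ranks, dtype=np.int64)
        n = len(self.genes)
        if self.ranks.shape != (n,):
            raise ValueError(
                f"instance {self.instance_id!r}: {self.ranks.shape} ranks for {n} genes"
            )
        if not np.array_equal(np.sort(self.ranks), np.arange(1, n + 1)):
            raise ValueError(
                f"instance {self.instance_id!r}: ranks are not a permutation of 1..{n}"
            )

    @property
    def n(self) -> int:
        return len(self.genes)

    def rank_map(self) -> dict[str, int]:
        return {g: int(r) for g, r in zip(self.genes, self.ranks)}

    @classmethod
    def from_mapping(
        cls, instance_id: str, drug_id: str, cell_line: str, mapping: dict[str, int]
    ) -> "RankProfile":
        genes = tuple(mapping)
        ranks = np.array([mapping[g] for g in genes], dtype=np.int64)
        return cls(instance_id, drug_id, cell_line, genes, ranks)


def reverse_profile(profile: RankProfile) -> RankProfile:
    """Flip the rank orientation (rank r -> n + 1 - r)."""
    return RankProfile(
        profile.instance_id,
        profile.drug_id,
        profile.cell_line,
        profile.genes,
        profile.n + 1 - profile.ranks,
    )


@dataclass
class ConnectivityResult:
    instance_id: str
    drug_id: str
    cell_line: str
    ks_up: float
    ks_down: float
    score: float
    p: float
    fdr: float
    significant_negative: bool


def _ks_sorted(v: np.ndarray, n: int) -> float:
    # v: sorted positions, validated upstream
    t = v.size
    j = np.arange(1, t + 1)
    a = (j / t - v / n).max()
    b = (v / n - (j - 1) / t).max()
    return float(a if a > b else -b)


def ks_statistic(positions, n: int) -> float:
    """Signed KS enrichment of a position set within ``1..n`` (positive = top)."""
    v = np.asarray(positions, dtype=np.int64)
    if v.size == 0:
        raise ValueError("ks_statistic: empty position set")
    if v.ndim != 1 or np.any(np.diff(v) <= 0):
        raise ValueError("ks_statistic: positions must be strictly increasing")
    if v[0] < 1 or v[-1] > n:
        raise ValueError(f"ks_statistic: positions must lie in 1..{n}")
    return _ks_sorted(v.astype(float), n)


def _combine(ks_up: float, ks_down: float) -> float:
    return ks_up - ks_down if ks_up * ks_down <= 0 else 0.0


def _signature_positions(
    gene_set, index: dict[str, int], ranks: np.ndarray, name: str, missing: str
):
    present = [g for g in sorted(gene_set) if g in index]
    absent = len(gene_set) - len(present)
    if absent:
        msg = f"{absent} {name}-signature gene(s) absent from the rank profile universe"
        if missing == "error":
            raise ValueError(msg)
        warnings.warn(msg + "; dropped", UserWarning, stacklevel=3)
    if not present:
        raise ValueError(f"no {name}-signature genes present in the profile universe")
    return np.sort(ranks[[index[g] for g in present]]).astype(float)


def connectivity_score(
    up, down, profile: RankProfile, missing: str = "drop"
) -> tuple[float, float, float]:
    """(ks_up, ks_down, score) of an up/down signature against one profile.

    ``missing`` controls signature genes absent from the profile universe:
    ``"drop"`` (default, with a warning) or ``"error"``.
    """
    up, down = set(up), set(down)
    if not up or not down:
        raise ValueError("up and down gene sets must be non-empty")
    if up & down:
        raise ValueError("up and down gene sets must be disjoint")
    index = {g: i for i, g in enumerate(profile.genes)}
    v_up = _signature_positions(up, index, profile.ranks, "up", missing)
    v_down = _signature_positions(down, index, profile.ranks, "down", missing)
    ks_up = _ks_sorted(v_up, profile.n)
    ks_down = _ks_sorted(v_down, profile.n)
    return ks_up, ks_down, _combine(ks_up, ks_down)


def _null_scores(
    n: int, t_up: int, t_down: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Permutation null: scores of random disjoint position sets of the given sizes."""
    out = np.empty(n_perm)
    t = t_up + t_down
    for i in range(n_perm):
        draw = rng.choice(n, size=t, replace=False) + 1
        ku = _ks_sorted(np.sort(draw[:t_up]).astype(float), n)
        kd = _ks_sorted(np.sort(draw[t_up:]).astype(float), n)
        out[i] = _combine(ku, kd)
    return out


def _check_n_perm(n_perm: int) -> None:
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives a coarse p-value resolution", UserWarning, stacklevel=3
        )


def connectivity_pvalue(
    up, down, profile: RankProfile, n_perm: int = 1000, seed=None, missing: str = "drop"
) -> float:
    """One-sided empirical p-value for negative connectivity.

    ``p = (1 + #{null score <= observed}) / (1 + n_perm)`` with null scores from
    random gene sets of the observed sizes drawn without replacement from the
    profile universe; never exactly zero.
    """
    _check_n_perm(n_perm)
    index = {g: i for i, g in enumerate(profile.genes)}
    up, down = set(up), set(down)
    if not up or not down:
        raise ValueError("up and down gene sets must be non-empty")
    if up & down:
        raise ValueError("up and down gene sets must be disjoint")
    v_up = _signature_positions(up, index, profile.ranks, "up", missing)
    v_down = _signature_positions(down, index, profile.ranks, "down", missing)
    obs = _combine(_ks_sorted(v_up, profile.n), _ks_sorted(v_down, profile.n))
    rng = np.random.default_rng(seed)
    null = _null_scores(profile.n, v_up.size, v_down.size, n_perm, rng)
    return float((1 + int((null <= obs).sum())) / (1 + n_perm))


def screen_instances(
    signature: DiseaseSignature,
    profiles: list[RankProfile],
    fdr_threshold: float = 0.1,
    n_perm: int = 1000,
    seed=None,
    missing: str = "drop",
) -> list[ConnectivityResult]:
    """Score every instance against the signature and flag significant reversers.

    All profiles must share one gene universe.  One permutation-null sample of
    size ``n_perm`` is shared by every instance (the null law of the score
    depends only on the set sizes and the universe size, not on the particular
    permutation), which also makes the p-values monotone in the observed score.
    BH adjustment runs across all instances of the screen;
    ``significant_negative`` requires ``fdr < fdr_threshold`` and ``score < 0``.
    """
    if not profiles:
        raise ValueError("screen_instances: no rank profiles supplied")
    _check_n_perm(n_perm)
    genes0 = profiles[0].genes
    for prof in profiles[1:]:
        if prof.genes != genes0:
            raise ValueError(
                f"instance {prof.instance_id!r} has a different gene universe"
            )
    n = len(genes0)
    index = {g: i for i, g in enumerate(genes0)}
    up_idx = [index[g] for g in sorted(signature.up) if g in index]
    down_idx = [index[g] for g in sorted(signature.down) if g in index]
    absent = (len(signature.up) - len(up_idx)) + (len(signature.down) - len(down_idx))
    if absent:
        msg = f"{absent} signature gene(s) absent from the rank profile universe"
        if missing == "error":
            raise ValueError(msg)
        warnings.warn(msg + "; dropped", UserWarning, stacklevel=2)
    if not up_idx or not down_idx:
        raise ValueError("signature has no genes in the profile universe on one side")
    up_idx = np.asarray(up_idx)
    down_idx = np.asarray(down_idx)

    ks_up = np.empty(len(profiles))
    ks_down = np.empty(len(profiles))
    scores = np.empty(len(profiles))
    for i, prof in enumerate(profiles):
        ku = _ks_sorted(np.sort(prof.ranks[up_idx]).astype(float), n)
        kd = _ks_sorted(np.sort(prof.ranks[down_idx]).astype(float), n)
        ks_up[i], ks_down[i] = ku, kd
        scores[i] = _combine(ku, kd)

    rng = np.random.default_rng(seed)
    null = np.sort(_null_scores(n, up_idx.size, down_idx.size, n_perm, rng))
    p = (1 + np.searchsorted(null, scores, side="right")) / (1 + n_perm)
    fdr = bh_fdr(p)
    flags = (fdr < fdr_threshold) & (scores < 0)
    return [
        ConnectivityResult(
            prof.instance_id,
            prof.drug_id,
            prof.cell_line,
            float(ks_up[i]),
            float(ks_down[i]),
            float(scores[i]),
            float(p[i]),
            float(fdr[i]),
            bool(flags[i]),
        )
        for i, prof in enumerate(profiles)
    ]


# ---------------------------------------------------------------------------
# TSV interfaces


def results_to_frame(results: list[ConnectivityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "instance_id": [r.instance_id for r in results],
            "drug_id": [r.drug_id for r in results],
            "cell_line": [r.cell_line for r in results],
            "ks_up": [r.ks_up for r in results],
            "ks_down": [r.ks_down for r in results],
            "score": [r.score for r in results],
            "p": [r.p for r in results],
            "fdr": [r.fdr for r in results],
            "significant_negative": [r.significant_negative for r in results],
        }
    )


def write_screen_results(results: list[ConnectivityResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def read_screen_results(path) -> list[ConnectivityResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        ConnectivityResult(
            str(row.instance_id),
            str(row.drug_id),
            str(row.cell_line),
            float(row.ks_up),
            float(row.ks_down),
            float(row.score),
            float(row.p),
            float(row.fdr),
            bool(row.significant_negative),
        )
        for row in df.itertuples(index=False)
    ]


def write_rank_profiles(profiles: list[RankProfile], ranks_path, meta_path) -> None:
    """Write a genes x instances integer rank matrix plus instance metadata."""
    if not profiles:
        raise ValueError("no profiles to write")
    genes = profiles[0].genes
    mat = pd.DataFrame(
        {p.instance_id: p.ranks for p in profiles}, index=pd.Index(genes, name="gene")
    )
    mat.to_csv(ranks_path, sep="\t")
    meta = pd.DataFrame(
        {
            "instance_id": [p.instance_id for p in profiles],
            "drug_id": [p.drug_id for p in profiles],
            "cell_line": [p.cell_line for p in profiles],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def read_rank_profiles(ranks_path, meta_path) -> list[RankProfile]:
    mat = pd.read_csv(ranks_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    genes = tuple(str(g) for g in mat.index)
    by_id = {row.instance_id: row for row in meta.itertuples(index=False)}
    profiles = []
    for col in mat.columns:
        if col not in by_id:
            raise ValueError(f"instance {col!r} missing from metadata {meta_path}")
        row = by_id[col]
        profiles.append(
            RankProfile(col, row.drug_id, row.cell_line, genes, mat[col].to_numpy())
        )
    return profiles
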