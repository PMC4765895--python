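"""End-to-end orchestration: expression -> connectivity screens and key-enzyme
prediction per dataset, then PUD combination, KPC intersection, candidate
selection and the overlap randomization test."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityResult, RankProfile, screen_instances
from .expression import DiseaseSignature, ExpressionDataset, differential_expression, normalize
from .metexpress import (
    ImportanceScore,
    MetabolicModel,
    ModulePartition,
    build_coexpression_network,
    importance_scores,
    key_enzymes,
    partition_modules,
    score_modules,
)
from .selection import (
    CandidateDrug,
    DrugAnnotationTable,
    kpc_intersection,
    overlap_randomization,
    puds_overall,
    puds_per_dataset,
    select_candidates,
)
from .simulate import GroundTruth, SyntheticStudy

__all__ = ["DatasetAnalysis", "StudyAnalysis", "analyze_datasets", "analyze_study", "evaluate_against_truth"]


@dataclass
class DatasetAnalysis:
    dataset_id: str
    signature: DiseaseSignature
    screen: list[ConnectivityResult]
    puds: set[str]
    partition: ModulePartition
    scores: list[ImportanceScore]
    keys: set[str]


@dataclass
class StudyAnalysis:
    per_dataset: list[DatasetAnalysis]
    puds: set[str]
    kpc: set[str]
    candidates: list[CandidateDrug]
    overlap_p_at_least_2: float
    overlap_p_all: float
    params: dict = field(default_factory=dict)


def analyze_datasets(
    datasets: list[ExpressionDataset],
    profiles: list[RankProfile],
    model: MetabolicModel,
    *,
    alpha: float = 0.01,
    fc_threshold: float = 2.0,
    fdr_connectivity: float = 0.1,
    min_abs_pcc: float = 0.7,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[DatasetAnalysis]:
    """Run the per-dataset stages: DE signature, connectivity screen, PUDs,
    co-expression modules, module AUCs, importance scores and key enzymes."""
    out = []
    seeds = np.random.SeedSequence(seed).spawn(len(datasets))
    for ds, ss in zip(datasets, seeds):
        screen_seed, louvain_seed = [int(s) % (2**31) for s in ss.generate_state(2)]
        nds = normalize(ds)
        sig = differential_expression(nds, alpha=alpha, fc_threshold=fc_threshold)
        screen = screen_instances(
            sig, profiles, fdr_threshold=fdr_connectivity, n_perm=n_perm, seed=screen_seed
        )
        puds = puds_per_dataset(screen)
        net = build_coexpression_network(nds, min_abs_pcc=min_abs_pcc)
        partition = score_modules(partition_modules(net, seed=louvain_seed), nds)
        scores = importance_scores(partition, model)
        keys = key_enzymes(scores)
        out.append(
            DatasetAnalysis(
                dataset_id=ds.dataset_id,
                signature=sig,
                screen=screen,
                puds=puds,
                partition=partition,
                scores=scores,
                keys=keys,
            )
        )
    return out


def analyze_study(
    datasets: list[ExpressionDataset],
    profiles: list[RankProfile],
    model: MetabolicModel,
    drug_table: DrugAnnotationTable,
    *,
    alpha: float = 0.01,
    fc_threshold: float = 2.0,
    fdr_connectivity: float = 0.1,
    min_abs_pcc: float = 0.7,
    n_perm: int = 1000,
    n_rand: int = 1000,
    min_datasets: int = 2,
    seed: int = 0,
) -> StudyAnalysis:
    """Full combined analysis across all datasets down to candidate drugs."""
    per_dataset = analyze_datasets(
        datasets,
        profiles,
        model,
        alpha=alpha,
        fc_threshold=fc_threshold,
        fdr_connectivity=fdr_connectivity,
        min_abs_pcc=min_abs_pcc,
        n_perm=n_perm,
        seed=seed,
    )
    pud_sets = [a.puds for a in per_dataset]
    puds = puds_overall(pud_sets, min_datasets=min_datasets)
    drug_universe = sorted({p.drug_id for p in profiles})
    rand_seed = int(np.random.SeedSequence([seed, 999]).generate_state(1)[0]) % (2**31)
    p2, p_all = overlap_randomization(pud_sets, drug_universe, n_rand=n_rand, seed=rand_seed)
    kpc = kpc_intersection([a.keys for a in per_dataset])
    candidates = select_candidates(puds, kpc, drug_table, model)
    return StudyAnalysis(
        per_dataset=per_dataset,
        puds=puds,
        kpc=kpc,
        candidates=candidates,
        overlap_p_at_least_2=p2,
        overlap_p_all=p_all,
        params={
            "alpha": alpha,
            "fc_threshold": fc_threshold,
            "fdr_connectivity": fdr_connectivity,
            "min_abs_pcc": min_abs_pcc,
            "n_perm": n_perm,
            "n_rand": n_rand,
            "min_datasets": min_datasets,
            "seed": seed,
        },
    )


def _safe_ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def evaluate_against_truth(analysis: StudyAnalysis, truth: GroundTruth) -> dict[str, float]:
    """Recovery metrics of the analysis against the planted ground truth."""
    reversers = set(truth.planted_reverser_drugs)
    planted_keys = set(truth.planted_key_enzymes)
    planted_candidates = set(truth.planted_candidate_drugs)
    selected = {c.drug_id for c in analysis.candidates}
    return {
        "pud_sensitivity": _safe_ratio(len(analysis.puds & reversers), len(reversers)),
        "pud_precision": _safe_ratio(len(analysis.puds & reversers), len(analysis.puds)),
        "key_enzyme_sensitivity": _safe_ratio(
            len(analysis.kpc & planted_keys), len(planted_keys)
        ),
        "candidate_precision": _safe_ratio(
            len(selected & planted_candidates), len(selected)
        ),
        "candidate_recall": _safe_ratio(
            len(selected & planted_candidates), len(planted_candidates)
        ),
    }


def analyze_synthetic_study(study: SyntheticStudy, **kwargs) -> StudyAnalysis:
    """Convenience wrapper: run the full analysis on a generated study."""
    return analyze_study(
        study.datasets, study.profiles, study.model, study.drug_table, **kwargs
    )
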