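"""Candidate-drug selection: combine per-dataset connectivity screens into
potentially useful drugs (PUDs), intersect per-dataset key-enzyme predictions,
filter PUDs by drug-target / substrate-product relations to the key enzymes,
and run the supporting randomization and enrichment tests.

A drug is potentially useful for one dataset when strictly more than half of
its treatment instances are significantly negatively correlated with the
disease signature; PUDs overall are drugs potentially useful in at least
``min_datasets`` datasets.  A PUD becomes a candidate when one of its targets
is a key enzyme ("target" route) or one of its compounds is a substrate or
product of a reaction catalyzed by a key enzyme ("metabolite" route); a drug
satisfying both reports the target route.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityResult
from .expression import bh_fdr
from .metexpress import MetabolicModel

TARGET_ROUTE = "target_of_kpc"
METABOLITE_ROUTE = "substrate_or_product_of_kpc"

__all__ = [
    "DrugAnnotation",
    "DrugAnnotationTable",
    "CandidateDrug",
    "TARGET_ROUTE",
    "METABOLITE_ROUTE",
    "puds_per_dataset",
    "puds_overall",
    "overlap_randomization",
    "kpc_intersection",
    "select_candidates",
    "fisher_enrichment",
    "read_drug_table",
    "write_drug_table",
    "read_gmt",
    "write_gmt",
    "candidates_to_frame",
    "write_candidates",
]


@dataclass(frozen=True)
class DrugAnnotation:
    drug_id: str
    targets: frozenset[str]
    compounds: frozenset[str]


@dataclass
class DrugAnnotationTable:
    """Per-drug target genes and compound ids (unique drug ids)."""

    drugs: dict[str, DrugAnnotation]

    def __post_init__(self) -> None:
        for drug_id, ann in self.drugs.items():
            if drug_id != ann.drug_id:
                raise ValueError(f"table key {drug_id!r} != annotation id {ann.drug_id!r}")

    @classmethod
    def from_records(cls, records) -> "DrugAnnotationTable":
        drugs: dict[str, DrugAnnotation] = {}
        for ann in records:
            if ann.drug_id in drugs:
                raise ValueError(f"duplicated drug id {ann.drug_id!r}")
            drugs[ann.drug_id] = ann
        return cls(drugs=drugs)

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.drugs

    def __getitem__(self, drug_id: str) -> DrugAnnotation:
        return self.drugs[drug_id]

    def __len__(self) -> int:
        return len(self.drugs)


@dataclass(frozen=True)
class CandidateDrug:
    drug_id: str
    rationale: str
    relevant_enzymes: frozenset[str]
    relevant_compounds: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.rationale not in (TARGET_ROUTE, METABOLITE_ROUTE):
            raise ValueError(f"unknown rationale {self.rationale!r}")
        if self.rationale == TARGET_ROUTE and self.relevant_compounds:
            raise ValueError("target-route candidates carry no compound evidence")
        if not self.relevant_enzymes:
            raise ValueError(f"candidate {self.drug_id!r} has no supporting enzymes")


def puds_per_dataset(results: list[ConnectivityResult]) -> set[str]:
    """Drugs with a significant negative correlation in strictly more than half
    of their instances."""
    n_inst: Counter = Counter()
    n_sig: Counter = Counter()
    for r in results:
        n_inst[r.drug_id] += 1
        if r.significant_negative:
            n_sig[r.drug_id] += 1
    return {d for d, n in n_inst.items() if n_sig[d] / n > 0.5}


def puds_overall(per_dataset_sets, min_datasets: int = 2) -> set[str]:
    """Drugs appearing in at least ``min_datasets`` of the per-dataset sets."""
    sets = [set(s) for s in per_dataset_sets]
    if not sets:
        raise ValueError("need at least one per-dataset drug set")
    if min_datasets > len(sets):
        raise ValueError(
            f"min_datasets={min_datasets} exceeds the {len(sets)} dataset sets supplied"
        )
    counts = Counter(d for s in sets for d in s)
    return {d for d, c in counts.items() if c >= min_datasets}


def _overlap_counts(sets: list[set]) -> tuple[int, int]:
    counts = Counter(d for s in sets for d in s)
    at_least_2 = sum(1 for c in counts.values() if c >= 2)
    in_all = sum(1 for c in counts.values() if c == len(sets))
    return at_least_2, in_all


def overlap_randomization(
    per_dataset_sets, universe, n_rand: int = 1000, seed=None
) -> tuple[float, float]:
    """Permutation p-values for the >=2-dataset and all-dataset drug overlaps.

    Each replicate draws, for every dataset, the same number of drugs uniformly
    without replacement from the universe and recounts the overlaps;
    ``p = (1 + #{null >= observed}) / (1 + n_rand)`` for each statistic.
    """
    sets = [set(s) for s in per_dataset_sets]
    if not sets:
        raise ValueError("need at least one per-dataset drug set")
    if n_rand <= 0:
        raise ValueError("n_rand must be positive")
    uni = sorted(set(universe))
    for i, s in enumerate(sets):
        extra = s - set(uni)
        if extra:
            raise ValueError(f"set {i} contains drugs outside the universe: {sorted(extra)[:5]}")
        if len(s) > len(uni):
            raise ValueError(f"set {i} is larger than the universe")
    obs2, obs_all = _overlap_counts(sets)
    rng = np.random.default_rng(seed)
    m = len(uni)
    ge2 = ge_all = 0
    for _ in range(n_rand):
        rand_sets = [set(rng.choice(m, size=len(s), replace=False).tolist()) for s in sets]
        n2, nall = _overlap_counts(rand_sets)
        ge2 += n2 >= obs2
        ge_all += nall >= obs_all
    return (
        float((1 + ge2) / (1 + n_rand)),
        float((1 + ge_all) / (1 + n_rand)),
    )


def kpc_intersection(key_sets) -> set[str]:
    """Genes predicted key in every dataset (intersection of all sets)."""
    sets = [set(s) for s in key_sets]
    if not sets:
        raise ValueError("need at least one key-enzyme set")
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def select_candidates(
    puds, kpc, drugs: DrugAnnotationTable, model: MetabolicModel
) -> list[CandidateDrug]:
    """Filter PUDs by their relation to the key (KPC) enzymes.

    Target route: a drug target is a KPC enzyme.  Metabolite route: a drug
    compound is a substrate or product of a reaction catalyzed by a KPC enzyme.
    A drug satisfying both reports the target route (the two rationale
    categories are exclusive).  PUDs absent from the annotation table are
    skipped with a warning.
    """
    kpc = set(kpc)
    compound_to_enzymes: dict[str, set[str]] = {}
    for r in model.reactions:
        if r.enzyme in kpc:
            for c in r.substrates | r.products:
                compound_to_enzymes.setdefault(c, set()).add(r.enzyme)

    candidates = []
    unannotated = []
    for drug_id in sorted(set(puds)):
        if drug_id not in drugs:
            unannotated.append(drug_id)
            continue
        ann = drugs[drug_id]
        target_hits = ann.targets & kpc
        if target_hits:
            candidates.append(
                CandidateDrug(drug_id, TARGET_ROUTE, frozenset(target_hits))
            )
            continue
        compound_hits = {c for c in ann.compounds if c in compound_to_enzymes}
        if compound_hits:
            enzymes = frozenset().union(*(compound_to_enzymes[c] for c in compound_hits))
            candidates.append(
                CandidateDrug(drug_id, METABOLITE_ROUTE, enzymes, frozenset(compound_hits))
            )
    if unannotated:
        warnings.warn(
            f"{len(unannotated)} PUD(s) absent from the drug annotation table; skipped",
            UserWarning,
            stacklevel=2,
        )
    return candidates


def fisher_enrichment(
    query, annotation_sets: dict, universe, fdr_threshold: float = 0.1
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of a gene set against named annotations.

    Each annotation set is intersected with the universe and tested with a 2x2
    table (in/out query x in/out set) under the enrichment alternative; BH
    adjustment across sets; ``significant`` marks ``fdr < fdr_threshold``.
    """
    query = set(query)
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query gene set")
    if query - uni:
        raise ValueError("query genes must be contained in the universe")
    names = sorted(annotation_sets)
    rows = []
    for name in names:
        s = set(annotation_sets[name]) & uni
        a = len(query & s)
        b = len(query) - a
        c = len(s) - a
        d = len(uni) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((name, len(s), a, float(p)))
    df = pd.DataFrame(rows, columns=["term", "set_size", "overlap", "p"])
    if len(df):
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["fdr"] < fdr_threshold
        df = df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    else:
        df["fdr"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


# ---------------------------------------------------------------------------
# TSV / GMT interfaces


def read_drug_table(path) -> DrugAnnotationTable:
    """Drug annotation TSV: drug_id, targets, compounds (``;``-joined lists)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"drug_id", "targets", "compounds"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    records = [
        DrugAnnotation(
            drug_id=row.drug_id,
            targets=frozenset(t for t in row.targets.split(";") if t),
            compounds=frozenset(c for c in row.compounds.split(";") if c),
        )
        for row in df.itertuples(index=False)
    ]
    return DrugAnnotationTable.from_records(records)


def write_drug_table(table: DrugAnnotationTable, path) -> None:
    drugs = [table.drugs[d] for d in sorted(table.drugs)]
    pd.DataFrame(
        {
            "drug_id": [d.drug_id for d in drugs],
            "targets": [";".join(sorted(d.targets)) for d in drugs],
            "compounds": [";".join(sorted(d.compounds)) for d in drugs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set file: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: GMT lines need name, description, genes")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{line_no}: duplicated set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def candidates_to_frame(candidates: list[CandidateDrug]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "drug_id": [c.drug_id for c in candidates],
            "rationale": [c.rationale for c in candidates],
            "relevant_enzymes": [";".join(sorted(c.relevant_enzymes)) for c in candidates],
            "relevant_compounds": [
                ";".join(sorted(c.relevant_compounds)) for c in candidates
            ],
        }
    )


def write_candidates(candidates: list[CandidateDrug], path) -> None:
    candidates_to_frame(candidates).to_csv(path, sep="\t", index=False)
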