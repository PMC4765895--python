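"""Synthetic study generator with planted ground truth.

Emulates the statistical structure the analysis assumes, end to end, so every
downstream stage is testable without any external download:

* case/control expression datasets with latent-factor co-expression modules
  (some cancer-specific), planted differentially expressed genes, and
  missing-at-random entries;
* drug rank profiles in which a planted subset of "reverser" drugs pushes the
  disease-up genes toward the bottom ranks and the disease-down genes toward
  the top;
* a metabolic reaction network in which planted key enzymes, placed inside
  cancer-specific modules, act as product-to-substrate hubs for co-module
  enzymes while background enzymes link sparsely and across modules;
* drug annotations wiring a subset of the reversers to the planted key enzymes
  either through a target gene or through a substrate/product compound.

Every generator is deterministic given the configuration seed; each stage uses
its own spawned stream so the stages can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .connectivity import RankProfile, write_rank_profiles
from .expression import CANCER, NORMAL, DiseaseSignature, ExpressionDataset
from .metexpress import MetabolicModel, ModulePartition, Reaction, write_reactions
from .selection import (
    METABOLITE_ROUTE,
    TARGET_ROUTE,
    DrugAnnotation,
    DrugAnnotationTable,
    write_drug_table,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticStudy",
    "gene_universe",
    "drug_universe",
    "generate_expression",
    "generate_rank_profiles",
    "generate_metabolic_model",
    "generate_drug_annotations",
    "planted_signature",
    "generate_study",
    "write_study",
]

# per-stage RNG stream tags (seed sequence = [tag, config.seed])
_EXPR, _RANKS, _METAB, _DRUGS = 1, 2, 3, 4


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults reproduce the planted-signal design exercised throughout: three
    case/control datasets of 2,000 genes with 30+30 samples, four co-expression
    modules of 30-60 genes (two cancer-specific with latent-factor mean shift
    ``cancer_module_effect``), 5% planted DE genes shifted by ``de_effect``
    log2 units, 200 drugs x 5 cell-line instances with 10 signature-reversing
    drugs of strength ``reversal_strength``, 100 enzyme genes with 10 planted
    keys, and 6 planted candidate drugs.
    """

    n_genes: int = 2000
    n_normal: int = 30
    n_cancer: int = 30
    n_datasets: int = 3
    n_modules: int = 4
    module_size_range: tuple[int, int] = (30, 60)
    n_cancer_modules: int = 2
    cancer_module_effect: float = 2.0  # latent-factor mean shift in cancer samples
    noise_sd: float = 0.5
    de_fraction: float = 0.05
    de_effect: float = 3.0  # log2 shift of planted DE genes in cancer samples
    n_drugs: int = 200
    instances_per_drug: int = 5
    n_reversers: int = 10
    reversal_strength: float = 2.0
    n_enzymes: int = 100
    n_reactions: int = 80  # background-reaction budget (base + cross-link filler)
    n_planted_key_enzymes: int = 10
    partners_per_key: int = 4
    n_planted_candidates: int = 6
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_normal": self.n_normal,
            "n_cancer": self.n_cancer,
            "n_datasets": self.n_datasets,
            "n_modules": self.n_modules,
            "n_drugs": self.n_drugs,
            "instances_per_drug": self.instances_per_drug,
            "n_enzymes": self.n_enzymes,
            "n_reactions": self.n_reactions,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive (got {value})")
        for name, value in (
            ("n_reversers", self.n_reversers),
            ("n_planted_key_enzymes", self.n_planted_key_enzymes),
            ("n_planted_candidates", self.n_planted_candidates),
            ("partners_per_key", self.partners_per_key),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0 (got {value})")
        lo, hi = self.module_size_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid module_size_range {self.module_size_range}")
        if self.n_modules * hi > self.n_genes:
            raise ValueError(
                f"{self.n_modules} modules of up to {hi} genes exceed n_genes={self.n_genes}"
            )
        if not 0 < self.de_fraction < 1:
            raise ValueError(f"de_fraction must lie in (0, 1) (got {self.de_fraction})")
        if not 0 <= self.missing_rate < 1:
            raise ValueError(f"missing_rate must lie in [0, 1) (got {self.missing_rate})")
        if not 0 <= self.n_cancer_modules <= self.n_modules:
            raise ValueError("n_cancer_modules must lie in 0..n_modules")
        if not self.n_planted_key_enzymes <= self.n_enzymes <= self.n_genes:
            raise ValueError(
                "need n_planted_key_enzymes <= n_enzymes <= n_genes "
                f"(got {self.n_planted_key_enzymes}, {self.n_enzymes}, {self.n_genes})"
            )
        if self.n_reversers > self.n_drugs:
            raise ValueError("n_reversers cannot exceed n_drugs")
        if self.n_planted_candidates > self.n_reversers:
            raise ValueError(
                f"n_planted_candidates={self.n_planted_candidates} exceeds "
                f"n_reversers={self.n_reversers}"
            )
        if self.reversal_strength < 0:
            raise ValueError("reversal_strength must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class GroundTruth:
    """Planted structure shared by the generators.

    ``planted_modules`` maps module genes to planted module ids;
    ``loadings`` holds the latent-factor loadings of module genes;
    ``planted_candidate_drugs`` maps each planted candidate to its rationale
    label; ``candidate_enzymes`` records the planted key enzyme wired to each
    candidate.
    """

    gene_universe: tuple[str, ...] = ()
    planted_modules: dict[str, str] = field(default_factory=dict)
    cancer_modules: frozenset[str] = frozenset()
    loadings: dict[str, float] = field(default_factory=dict)
    planted_de_up: dict[str, frozenset[str]] = field(default_factory=dict)
    planted_de_down: dict[str, frozenset[str]] = field(default_factory=dict)
    planted_reverser_drugs: frozenset[str] = frozenset()
    planted_key_enzymes: frozenset[str] = frozenset()
    enzyme_genes: tuple[str, ...] = ()
    planted_candidate_drugs: dict[str, str] = field(default_factory=dict)
    candidate_enzymes: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not set(self.planted_candidate_drugs) <= set(self.planted_reverser_drugs):
            raise ValueError("planted candidates must be a subset of the reversers")
        if self.enzyme_genes and not set(self.planted_key_enzymes) <= set(self.enzyme_genes):
            raise ValueError("planted key enzymes must be enzyme genes")

    def to_json(self) -> str:
        def _default(value):
            if isinstance(value, (set, frozenset)):
                return sorted(value)
            raise TypeError(f"not JSON serializable: {type(value)}")

        return json.dumps(asdict(self), indent=2, sort_keys=True, default=_default)


def gene_universe(config: SimulationConfig) -> tuple[str, ...]:
    return tuple(f"G{i:04d}" for i in range(config.n_genes))


def drug_universe(config: SimulationConfig) -> tuple[str, ...]:
    return tuple(f"D{i:03d}" for i in range(1, config.n_drugs + 1))


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Latent-factor case/control datasets with planted modules and DE genes.

    Per dataset: baseline gene means ~ Normal(8, 1.5^2) on the log2 scale; each
    module has a per-sample factor ~ Normal(0, 1) (shifted by the cancer effect
    in cancer samples of cancer-specific modules); module gene expression adds
    ``loading * factor`` with loadings ~ Uniform(0.5, 1.5) shared across
    datasets; planted DE genes (sampled outside the modules) are shifted by
    +/- ``de_effect`` in cancer samples; entries go missing completely at
    random at ``missing_rate``.  The same gene universe and planted structure
    are used in every dataset.
    """
    config.validate()
    rng = np.random.default_rng([_EXPR, config.seed])
    truth = truth if truth is not None else GroundTruth()
    genes = gene_universe(config)
    n_genes = config.n_genes

    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi, endpoint=True, size=config.n_modules)
    if sizes.sum() > n_genes:
        raise ValueError(
            f"module sizes {sizes.tolist()} exceed the {n_genes}-gene universe"
        )
    order = rng.permutation(n_genes)
    module_ids = [f"PM{k + 1}" for k in range(config.n_modules)]
    cancer_modules = frozenset(module_ids[: config.n_cancer_modules])
    module_rows: dict[str, np.ndarray] = {}
    offset = 0
    for mid, size in zip(module_ids, sizes):
        module_rows[mid] = np.sort(order[offset : offset + size])
        offset += int(size)
    background_rows = order[offset:]

    n_de = int(round(config.de_fraction * n_genes))
    if n_de > background_rows.size:
        raise ValueError(
            f"{n_de} planted DE genes requested but only {background_rows.size} "
            "genes remain outside the modules"
        )
    if n_de < 2:
        raise ValueError("de_fraction too small: need at least one up and one down gene")
    de_rows = background_rows[:n_de]  # background_rows is already randomly ordered
    up_rows = de_rows[: n_de // 2 + n_de % 2]
    down_rows = de_rows[n_de // 2 + n_de % 2 :]

    loadings = rng.uniform(0.5, 1.5, size=n_genes)
    truth.gene_universe = genes
    truth.planted_modules = {
        genes[i]: mid for mid, rows in module_rows.items() for i in rows
    }
    truth.cancer_modules = cancer_modules
    truth.loadings = {
        genes[i]: float(loadings[i]) for rows in module_rows.values() for i in rows
    }

    n_samples = config.n_normal + config.n_cancer
    cancer_cols = np.arange(config.n_normal, n_samples)
    phenotype = [NORMAL] * config.n_normal + [CANCER] * config.n_cancer

    datasets = []
    for k in range(config.n_datasets):
        dataset_id = f"DS{k + 1}"
        samples = [
            f"{dataset_id}_{'N' if lab == NORMAL else 'C'}{j + 1:02d}"
            for j, lab in enumerate(phenotype)
        ]
        mu = rng.normal(8.0, 1.5, size=n_genes)
        X = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))
        for mid, rows in module_rows.items():
            f = rng.normal(0.0, 1.0, size=n_samples)
            if mid in cancer_modules:
                f[cancer_cols] += config.cancer_module_effect
            X[rows] += loadings[rows, None] * f[None, :]
        X[np.ix_(up_rows, cancer_cols)] += config.de_effect
        X[np.ix_(down_rows, cancer_cols)] -= config.de_effect
        if config.missing_rate > 0:
            mask = rng.random(X.shape) < config.missing_rate
            X[mask] = np.nan
        datasets.append(
            ExpressionDataset(dataset_id, list(genes), samples, X, phenotype)
        )
        truth.planted_de_up[dataset_id] = frozenset(genes[i] for i in up_rows)
        truth.planted_de_down[dataset_id] = frozenset(genes[i] for i in down_rows)
    return datasets, truth


def planted_signature(truth: GroundTruth, de_effect: float = 3.0) -> DiseaseSignature:
    """The planted disease signature (identical across datasets by design)."""
    import pandas as pd

    if not truth.planted_de_up:
        raise ValueError("ground truth has no planted DE genes")
    first = sorted(truth.planted_de_up)[0]
    up = truth.planted_de_up[first]
    down = truth.planted_de_down[first]
    members = sorted(up) + sorted(down)
    lfc = pd.Series(
        [de_effect] * len(up) + [-de_effect] * len(down),
        index=pd.Index(members, name="gene"),
        dtype=float,
    )
    zeros = pd.Series(0.0, index=lfc.index)
    return DiseaseSignature(up=up, down=down, log2fc=lfc, pvalue=zeros, fdr=zeros)


# ---------------------------------------------------------------------------
# rank profiles


def generate_rank_profiles(
    config: SimulationConfig,
    signature: DiseaseSignature,
    truth: GroundTruth | None = None,
) -> tuple[list[RankProfile], GroundTruth]:
    """Drug rank profiles with planted signature-reversing drugs.

    Per instance, every gene receives a score ``eps ~ Normal(0, 1)``; for
    reverser drugs the score is ``-beta * s_g + eps`` with ``s_g = +1`` for
    disease-up genes, ``-1`` for disease-down genes and 0 otherwise.  Ranks are
    assigned by descending score (rank 1 = most drug-up-regulated), so a
    reverser pushes disease-up genes to the bottom and disease-down genes to
    the top of its lists.
    """
    config.validate()
    if not signature.up and not signature.down:
        raise ValueError("empty disease signature")
    truth = truth if truth is not None else GroundTruth()
    genes = gene_universe(config)
    index = {g: i for i, g in enumerate(genes)}
    outside = (set(signature.up) | set(signature.down)) - set(genes)
    if outside:
        raise ValueError(
            f"signature genes outside the simulated universe: {sorted(outside)[:5]}"
        )
    s = np.zeros(config.n_genes)
    s[[index[g] for g in signature.up]] = 1.0
    s[[index[g] for g in signature.down]] = -1.0

    rng = np.random.default_rng([_RANKS, config.seed])
    drugs = drug_universe(config)
    reversers = frozenset(
        rng.choice(drugs, size=config.n_reversers, replace=False).tolist()
    )
    cells = [f"CL{j}" for j in range(1, config.instances_per_drug + 1)]
    beta = config.reversal_strength

    profiles = []
    ranks_template = np.arange(1, config.n_genes + 1)
    for drug in drugs:
        is_reverser = drug in reversers
        for cell in cells:
            score = rng.standard_normal(config.n_genes)
            if is_reverser:
                score -= beta * s
            order = np.argsort(-score, kind="stable")
            ranks = np.empty(config.n_genes, dtype=np.int64)
            ranks[order] = ranks_template
            profiles.append(RankProfile(f"{drug}.{cell}", drug, cell, genes, ranks))
    truth.planted_reverser_drugs = reversers
    return profiles, truth


# ---------------------------------------------------------------------------
# metabolic model


def _upper_loading_pool(
    genes: list[str], loadings: dict[str, float] | None, need: int
) -> list[str]:
    """Top-loading module genes (strong, detectable co-expression).

    Returns the upper-loading half of the module, extended to ``need`` genes
    (still highest loadings first) when the half is too small.
    """
    if not loadings:
        return sorted(genes)
    ranked = sorted(genes, key=lambda g: (-loadings.get(g, 0.0), g))
    take = max(len(ranked) // 2, need, 1)
    return ranked[:take]


def generate_metabolic_model(
    config: SimulationConfig,
    modules: ModulePartition,
    cancer_module_ids,
    loadings: dict[str, float] | None = None,
    truth: GroundTruth | None = None,
) -> tuple[MetabolicModel, GroundTruth]:
    """Reaction network with planted key enzymes inside cancer-specific modules.

    Each planted key enzyme catalyzes one reaction whose product is consumed by
    ``partners_per_key`` co-module partner enzymes, giving the key a
    within-module product-to-substrate hub.  Keys and partners are drawn from
    the upper-loading half of their module so the planted truth corresponds to
    genuinely co-expressed enzymes.  Background enzymes (sampled outside the
    cancer modules) get fresh-compound reactions plus sparse cross links.
    """
    config.validate()
    truth = truth if truth is not None else GroundTruth()
    rng = np.random.default_rng([_METAB, config.seed])
    assignment = modules.assignment
    cancer_ids = sorted(set(cancer_module_ids))
    if config.n_planted_key_enzymes > 0 and not cancer_ids:
        raise ValueError("planted key enzymes require at least one cancer-specific module")
    module_genes: dict[str, list[str]] = {}
    for gene, mid in assignment.items():
        module_genes.setdefault(mid, []).append(gene)
    for mid in cancer_ids:
        if mid not in module_genes:
            raise ValueError(f"cancer module {mid!r} has no genes in the partition")

    # distribute keys across cancer modules as evenly as possible
    keys_per_module = {mid: 0 for mid in cancer_ids}
    for i in range(config.n_planted_key_enzymes):
        keys_per_module[cancer_ids[i % len(cancer_ids)]] += 1

    compound_counter = 0

    def fresh_compound() -> str:
        nonlocal compound_counter
        compound_counter += 1
        return f"C{compound_counter:04d}"

    reactions: list[Reaction] = []
    rid_counter = 0

    def add_reaction(enzyme: str, substrates, products) -> Reaction:
        nonlocal rid_counter
        rid_counter += 1
        r = Reaction(f"R{rid_counter:04d}", enzyme, frozenset(substrates), frozenset(products))
        reactions.append(r)
        return r

    keys: list[str] = []
    partners: list[str] = []
    key_substrate: dict[str, str] = {}
    for mid in cancer_ids:
        n_keys = keys_per_module[mid]
        if n_keys == 0:
            continue
        need = n_keys * (1 + config.partners_per_key)
        pool = _upper_loading_pool(module_genes[mid], loadings, need)
        if len(pool) < need:
            raise ValueError(
                f"cancer module {mid!r} has {len(pool)} genes but "
                f"{need} are needed for keys and partners"
            )
        chosen = rng.choice(pool, size=need, replace=False).tolist()
        module_keys = chosen[:n_keys]
        module_partners = chosen[n_keys:]
        for j, key in enumerate(module_keys):
            sub, prod = fresh_compound(), fresh_compound()
            add_reaction(key, [sub], [prod])
            key_substrate[key] = sub
            start = j * config.partners_per_key
            for partner in module_partners[start : start + config.partners_per_key]:
                add_reaction(partner, [prod], [fresh_compound()])
            keys.append(key)
        partners.extend(module_partners)

    n_background = config.n_enzymes - len(keys) - len(partners)
    if n_background < 0:
        raise ValueError(
            f"n_enzymes={config.n_enzymes} too small for {len(keys)} keys and "
            f"{len(partners)} partners"
        )
    cancer_genes = {g for mid in cancer_ids for g in module_genes.get(mid, ())}
    pool_universe = set(truth.gene_universe) if truth.gene_universe else set(assignment)
    bg_pool = sorted(pool_universe - cancer_genes - set(keys) - set(partners))
    if n_background > len(bg_pool):
        raise ValueError(
            f"{n_background} background enzymes requested but only {len(bg_pool)} genes available"
        )
    background = rng.choice(bg_pool, size=n_background, replace=False).tolist() if n_background else []
    if config.n_reactions < n_background:
        raise ValueError(
            f"n_reactions={config.n_reactions} cannot cover one base reaction per "
            f"background enzyme ({n_background})"
        )
    bg_products: list[tuple[str, str]] = []  # (enzyme, product compound)
    for enzyme in background:
        prod = fresh_compound()
        add_reaction(enzyme, [fresh_compound()], [prod])
        bg_products.append((enzyme, prod))
    # sparse cross links among background enzymes (mostly across modules)
    n_cross = config.n_reactions - n_background
    for _ in range(n_cross):
        if len(background) < 2:
            break
        producer, prod = bg_products[int(rng.integers(len(bg_products)))]
        consumer = background[int(rng.integers(len(background)))]
        if consumer == producer:
            continue
        add_reaction(consumer, [prod], [fresh_compound()])

    model = MetabolicModel(reactions=reactions)
    truth.planted_key_enzymes = frozenset(keys)
    truth.enzyme_genes = tuple(model.enzymes)
    truth._key_substrate = key_substrate  # consumed by generate_drug_annotations
    return model, truth


# ---------------------------------------------------------------------------
# drug annotations


def generate_drug_annotations(
    config: SimulationConfig,
    model: MetabolicModel,
    reversers,
    planted_key_enzymes=None,
    truth: GroundTruth | None = None,
) -> tuple[DrugAnnotationTable, GroundTruth]:
    """Drug targets/compounds with planted candidates among the reversers.

    A chosen subset of the reverser drugs is wired to the planted key enzymes:
    alternating drugs get a key enzyme as a target (target route) or a key
    reaction substrate as a compound (metabolite route).  All other drugs get
    1-3 background targets (never enzyme genes) and compounds that appear in no
    reaction, so they can never be selected.
    """
    config.validate()
    truth = truth if truth is not None else GroundTruth()
    reversers = sorted(set(reversers))
    if config.n_planted_candidates > len(reversers):
        raise ValueError(
            f"n_planted_candidates={config.n_planted_candidates} exceeds the "
            f"{len(reversers)} reverser drugs"
        )
    keys = sorted(
        planted_key_enzymes if planted_key_enzymes is not None else truth.planted_key_enzymes
    )
    if config.n_planted_candidates > 0 and not keys:
        raise ValueError("planted candidates require planted key enzymes")

    key_substrate: dict[str, str] = getattr(truth, "_key_substrate", {})
    if not key_substrate:
        for r in model.reactions:
            if r.enzyme in keys and r.enzyme not in key_substrate:
                key_substrate[r.enzyme] = sorted(r.substrates)[0]

    rng = np.random.default_rng([_DRUGS, config.seed])
    drugs = drug_universe(config)
    enzyme_set = set(model.enzymes)
    reaction_compounds = model.compounds()
    universe = list(gene_universe(config))
    bg_target_pool = sorted(set(universe) - enzyme_set)

    chosen = (
        rng.choice(reversers, size=config.n_planted_candidates, replace=False).tolist()
        if config.n_planted_candidates
        else []
    )
    target_route = set(chosen[0::2])
    metabolite_route = set(chosen[1::2])

    x_counter = 0

    def fresh_x() -> str:
        nonlocal x_counter
        x_counter += 1
        c = f"X{x_counter:04d}"
        assert c not in reaction_compounds
        return c

    records = []
    candidate_rationale: dict[str, str] = {}
    candidate_enzyme: dict[str, str] = {}
    route_assign = {d: keys[i % len(keys)] for i, d in enumerate(sorted(chosen))} if chosen else {}
    for drug in drugs:
        n_t = int(rng.integers(1, 4))
        targets = set(rng.choice(bg_target_pool, size=n_t, replace=False).tolist())
        compounds = {fresh_x()}
        if drug in target_route:
            key = route_assign[drug]
            targets.add(key)
            candidate_rationale[drug] = TARGET_ROUTE
            candidate_enzyme[drug] = key
        elif drug in metabolite_route:
            key = route_assign[drug]
            compounds.add(key_substrate[key])
            candidate_rationale[drug] = METABOLITE_ROUTE
            candidate_enzyme[drug] = key
        records.append(
            DrugAnnotation(drug, frozenset(targets), frozenset(compounds))
        )
    table = DrugAnnotationTable.from_records(records)
    truth.planted_candidate_drugs = candidate_rationale
    truth.candidate_enzymes = candidate_enzyme
    if not truth.planted_reverser_drugs:
        truth.planted_reverser_drugs = frozenset(reversers)
    truth.validate()
    return table, truth


# ---------------------------------------------------------------------------
# whole study


@dataclass
class SyntheticStudy:
    """One fully generated study: data, annotations and planted truth."""

    config: SimulationConfig
    datasets: list[ExpressionDataset]
    signature: DiseaseSignature  # planted (not estimated) disease signature
    profiles: list[RankProfile]
    model: MetabolicModel
    drug_table: DrugAnnotationTable
    truth: GroundTruth


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate every component of the synthetic study from one seed."""
    datasets, truth = generate_expression(config)
    signature = planted_signature(truth, de_effect=config.de_effect)
    profiles, truth = generate_rank_profiles(config, signature, truth)
    planted_partition = ModulePartition(assignment=dict(truth.planted_modules))
    model, truth = generate_metabolic_model(
        config,
        planted_partition,
        truth.cancer_modules,
        loadings=truth.loadings,
        truth=truth,
    )
    drug_table, truth = generate_drug_annotations(
        config, model, truth.planted_reverser_drugs, truth.planted_key_enzymes, truth
    )
    return SyntheticStudy(
        config=config,
        datasets=datasets,
        signature=signature,
        profiles=profiles,
        model=model,
        drug_table=drug_table,
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write the study in the same TSV formats the real-data readers consume."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in study.datasets:
        ds.to_frame().rename_axis("gene").to_csv(
            out / f"expression_{ds.dataset_id}.tsv", sep="\t"
        )
        with open(out / f"phenotype_{ds.dataset_id}.tsv", "w") as fh:
            for sample, label in zip(ds.samples, ds.phenotype):
                fh.write(f"{sample}\t{label}\n")
    write_rank_profiles(study.profiles, out / "ranks.tsv", out / "instances.tsv")
    write_reactions(study.model.reactions, out / "reactions.tsv")
    write_drug_table(study.drug_table, out / "drugs.tsv")
    (out / "ground_truth.json").write_text(study.truth.to_json() + "\n")
    (out / "config.json").write_text(
        json.dumps(asdict(study.config), indent=2, sort_keys=True) + "\n"
    )
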