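"""Synthetic inputs with planted ground truth for the radiation network pipeline.

Everything the pipeline consumes can be generated here: a paired
control/irradiated expression matrix, the four typed interaction tables of
the heterogeneous TF-miRNA-gene network, gene-set collections, molecule to
disease associations with a disease to category map, and compound reference
rank profiles.  Each generator plants a recoverable signal (differential
features, dense PPI cliques, enriched sets and diseases, one or more
signature-reversing compounds) and records it in a :class:`GroundTruth`, so
every downstream stage can be tested against known truth without external
databases.

Determinism: every generator draws from its own ``numpy`` Generator seeded
from ``(rng_seed, stream_offset)``, so regenerating one input never perturbs
another, and identical configs yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PairedExpressionSet",
    "generate_expression",
    "generate_interactome",
    "generate_annotations",
    "generate_all",
    "ground_truth",
]

# named RNG substreams; adding a generator must not reshuffle existing draws
_STREAMS = {"truth": 0, "expression": 1, "interactome": 2, "annotations": 3}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate a paired five-donor irradiation design at a reduced
    scale: a few thousand measured features, a minority of which carry a
    true log2 fold change of ±``effect_lfc``, heavier-tailed per-feature
    noise variances, and an interactome whose degree distribution is
    approximately power-law.
    """

    n_genes: int = 2000
    n_mirnas: int = 150
    n_tfs: int = 80
    n_donors: int = 5
    frac_true_de: float = 0.05
    effect_lfc: float = 2.0
    noise_sd: float = 0.5          # prior scale s0 of per-feature noise, log2 units
    rng_seed: int = 0
    interactome_density: float = 3.0   # expected edges per node, all layers combined
    confidence_range: tuple[float, float] = (0.5, 1.0)
    planted_module_sizes: tuple[int, ...] = (6, 5)
    n_compounds: int = 20
    n_diseases: int = 30
    n_categories: int = 12
    # secondary knobs (sizes of planted annotation structure)
    n_gene_sets: int = 34
    n_enriched_sets: int = 3
    n_enriched_diseases: int = 5
    n_reversal_compounds: int = 1
    var_prior_df: float = 4.0      # d0 of the scaled inverse-chi-square noise family

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes, "n_mirnas": self.n_mirnas,
            "n_tfs": self.n_tfs, "n_donors": self.n_donors,
            "n_compounds": self.n_compounds, "n_diseases": self.n_diseases,
            "n_categories": self.n_categories, "n_gene_sets": self.n_gene_sets,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not 0.0 <= self.frac_true_de <= 1.0:
            raise ValueError("frac_true_de must lie in [0, 1]")
        lo, hi = self.confidence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("confidence_range must be an interval within [0, 1]")
        if self.interactome_density <= 0:
            raise ValueError("interactome_density must be positive")
        for s in self.planted_module_sizes:
            if s < 2:
                raise ValueError("planted module sizes must be >= 2")
            if s > self.n_genes:
                raise ValueError(
                    f"planted module size {s} exceeds n_genes={self.n_genes}")
        if self.n_reversal_compounds > self.n_compounds:
            raise ValueError("more reversal compounds than compounds")

    # ---- id space -------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        w = len(str(self.n_genes))
        return [f"G{i:0{w}d}" for i in range(1, self.n_genes + 1)]

    @property
    def tf_ids(self) -> list[str]:
        w = len(str(self.n_tfs))
        return [f"TF{i:0{w}d}" for i in range(1, self.n_tfs + 1)]

    @property
    def mirna_ids(self) -> list[str]:
        w = len(str(self.n_mirnas))
        return [f"MIR{i:0{w}d}" for i in range(1, self.n_mirnas + 1)]

    @property
    def protein_ids(self) -> list[str]:
        """Protein-coding node ids (genes + TFs)."""
        return self.gene_ids + self.tf_ids

    @property
    def feature_ids(self) -> list[str]:
        """All measured features, proteins first then miRNAs."""
        return self.protein_ids + self.mirna_ids

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.rng_seed, _STREAMS[stream]])


@dataclass
class GroundTruth:
    """Planted signal, filled in incrementally by the generators."""

    true_de_features: dict[str, float] = field(default_factory=dict)
    planted_modules: list[frozenset[str]] = field(default_factory=list)
    reversal_compounds: set[str] = field(default_factory=set)
    enriched_sets: set[str] = field(default_factory=set)
    enriched_diseases: set[str] = field(default_factory=set)


@dataclass
class PairedExpressionSet:
    """log2 expression matrix (features x samples) with paired metadata."""

    values: pd.DataFrame
    feature_meta: pd.DataFrame   # feature_id, molecule_type in {gene, miRNA}
    sample_meta: pd.DataFrame    # sample_id, donor, condition

    def __post_init__(self) -> None:
        pairs = self.sample_meta.groupby("donor")["condition"].agg(set)
        bad = pairs[pairs != {"control", "irradiated"}]
        if len(bad):
            raise ValueError(
                f"donors without exactly one control/irradiated pair: {list(bad.index)}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")


def _planted_de(config: SimulationConfig) -> dict[str, float]:
    """Planted signed log2 fold changes, deterministic in the config alone.

    Count is round(frac_true_de * n_features); signs drawn 50/50.  Drawn from
    the dedicated 'truth' stream so expression, annotation and profile
    generators all agree on the planted set.
    """
    rng = config.rng("truth")
    features = config.feature_ids
    n_true = int(round(config.frac_true_de * len(features)))
    if n_true == 0 or config.effect_lfc == 0:
        return {}
    chosen = rng.choice(len(features), size=n_true, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_true)
    return {features[i]: s * config.effect_lfc for i, s in zip(sorted(chosen), signs)}


def ground_truth(config: SimulationConfig) -> GroundTruth:
    """Full planted truth for ``config`` without generating the data files."""
    config.validate()
    gt = GroundTruth(true_de_features=_planted_de(config))
    gt.planted_modules = _planted_cliques(config)
    gt.enriched_sets, gt.enriched_diseases, gt.reversal_compounds = _planted_annotations(config)
    return gt


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

def generate_expression(config: SimulationConfig) -> tuple[PairedExpressionSet, GroundTruth]:
    """Paired control/irradiated log2 expression with planted fold changes.

    Per-feature noise variances follow a scaled inverse-chi-square family
    s0^2 * d0 / chi2(d0), the variance model a moderated t-statistic assumes.
    The family is planted on the scale the test estimates — the per-donor
    difference variance — so a method-of-moments fit on the generated data
    recovers (d0, s0^2) directly; each individual sample carries half the
    difference variance.
    """
    config.validate()
    if config.n_donors < 2:
        raise ValueError("n_donors must be >= 2 (paired variance undefined otherwise)")
    rng = config.rng("expression")
    truth = _planted_de(config)

    features = config.feature_ids
    nf = len(features)
    lfc = np.array([truth.get(f, 0.0) for f in features])

    baseline = rng.normal(8.0, 2.0, size=nf)
    donor_shift = rng.normal(0.0, 0.5, size=config.n_donors)
    diff_var = (config.noise_sd ** 2) * config.var_prior_df / rng.chisquare(
        config.var_prior_df, size=nf)
    sd = np.sqrt(diff_var / 2.0)

    cols, data, meta_rows = [], [], []
    for d in range(1, config.n_donors + 1):
        for cond, effect in (("control", 0.0), ("irradiated", 1.0)):
            sid = f"donor{d}_{cond}"
            cols.append(sid)
            meta_rows.append((sid, f"donor{d}", cond))
            data.append(baseline + donor_shift[d - 1] + effect * lfc
                        + rng.normal(0.0, sd))
    values = pd.DataFrame(np.column_stack(data), index=pd.Index(features, name="feature_id"),
                          columns=cols)
    feature_meta = pd.DataFrame({
        "feature_id": features,
        "molecule_type": ["gene"] * len(config.protein_ids) + ["miRNA"] * config.n_mirnas,
    })
    sample_meta = pd.DataFrame(meta_rows, columns=["sample_id", "donor", "condition"])
    expr = PairedExpressionSet(values, feature_meta, sample_meta)
    gt = GroundTruth(true_de_features=truth)
    return expr, gt


# --------------------------------------------------------------------------
# interactome
# --------------------------------------------------------------------------

_EDGE_COLUMNS = ["source", "target", "source_type", "target_type",
                 "interaction_type", "confidence"]

# share of the total edge budget per interaction layer
_LAYER_BUDGET = {"ppi": 0.70, "mirna_gene": 0.20, "tf_gene": 0.08, "tf_mirna": 0.02}


def _planted_cliques(config: SimulationConfig) -> list[frozenset[str]]:
    rng = config.rng("truth")
    rng = np.random.default_rng(rng.integers(2 ** 31))  # sub-draw after DE choice
    genes = config.gene_ids
    total = sum(config.planted_module_sizes)
    chosen = rng.choice(len(genes), size=total, replace=False)
    out, pos = [], 0
    for s in config.planted_module_sizes:
        out.append(frozenset(genes[i] for i in chosen[pos:pos + s]))
        pos += s
    return out


def _sample_distinct_pairs(rng, n_pairs, draw_pair, existing, max_factor=60):
    """Draw ``n_pairs`` distinct unordered pairs not already in ``existing``."""
    pairs = []
    attempts = 0
    while len(pairs) < n_pairs and attempts < max_factor * max(n_pairs, 1):
        a, b = draw_pair(rng)
        attempts += 1
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        if key in existing:
            continue
        existing.add(key)
        pairs.append((a, b))
    return pairs


def generate_interactome(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Typed edge tables: 'tf_gene', 'mirna_gene', 'tf_mirna' and 'ppi'.

    The PPI layer grows by preferential attachment over the protein nodes
    (approximately power-law degrees, hub TFs emerge naturally); regulator
    edges attach TFs/miRNAs to genes with degree-proportional probability.
    Planted cliques are embedded in the PPI layer with confidences in the
    upper part of ``confidence_range`` so they survive a >0.7 filter whenever
    the range allows.  One self-loop and one duplicate PPI row are injected
    deliberately to exercise downstream cleaning.
    """
    import networkx as nx

    config.validate()
    rng = config.rng("interactome")
    genes, tfs, mirnas = config.gene_ids, config.tf_ids, config.mirna_ids
    proteins = config.protein_ids
    n_nodes = len(proteins) + len(mirnas)
    e_target = int(round(config.interactome_density * n_nodes))
    budget = {k: int(round(v * e_target)) for k, v in _LAYER_BUDGET.items()}

    # --- PPI backbone: Barabasi-Albert growth topped up to an exact budget
    n_p = len(proteins)
    m_ba = max(1, budget["ppi"] // n_p)
    ba = nx.barabasi_albert_graph(n_p, min(m_ba, n_p - 1),
                                  seed=int(rng.integers(2 ** 31)))
    perm = rng.permutation(n_p)  # random protein <-> BA-position assignment
    label = {i: proteins[perm[i]] for i in range(n_p)}
    existing = set()
    ppi_pairs = []
    for u, v in ba.edges():
        a, b = label[u], label[v]
        key = (a, b) if a <= b else (b, a)
        existing.add(key)
        ppi_pairs.append((a, b))
    # top up with degree-proportional extra edges until the budget is met
    deg = np.array([ba.degree(i) for i in range(n_p)], dtype=float)
    pdeg = deg / deg.sum()

    def draw_ppi(r):
        i, j = r.choice(n_p, size=2, p=pdeg)
        return label[i], label[j]

    ppi_pairs += _sample_distinct_pairs(rng, budget["ppi"] - len(ppi_pairs),
                                        draw_ppi, existing)
    lo, hi = config.confidence_range
    conf = rng.uniform(lo, hi, size=len(ppi_pairs))

    # --- planted cliques in the PPI layer, high confidence
    clique_lo = max(lo, min(0.75, hi))
    clique_pairs, clique_conf = [], []
    for clique in _planted_cliques(config):
        members = sorted(clique)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                key = (members[i], members[j])
                if key in existing:
                    continue
                existing.add(key)
                clique_pairs.append(key)
                clique_conf.append(rng.uniform(clique_lo, hi))

    ppi = pd.DataFrame(ppi_pairs + clique_pairs, columns=["source", "target"])
    ppi["source_type"] = [("TF" if s in set(tfs) else "gene") for s in ppi["source"]]
    ppi["target_type"] = [("TF" if t in set(tfs) else "gene") for t in ppi["target"]]
    ppi["interaction_type"] = "ppi"
    ppi["confidence"] = np.concatenate([conf, np.array(clique_conf)]) if clique_conf else conf
    # deliberate dirt: one self-loop and one duplicated row
    dirt = pd.DataFrame([
        [genes[0], genes[0], "gene", "gene", "ppi", float(hi)],
        list(ppi.iloc[0]),
    ], columns=_EDGE_COLUMNS)
    ppi = pd.concat([ppi, dirt], ignore_index=True)

    # degree-proportional gene choice for regulator layers
    pos_of = {proteins[perm[i]]: i for i in range(n_p)}
    gdeg = np.array([deg[pos_of[g]] for g in genes], dtype=float)
    gdeg = np.maximum(gdeg, 1.0)
    pgene = gdeg / gdeg.sum()

    def make_reg(layer, left_ids, left_type, n_edges):
        seen = set()

        def draw(r):
            a = left_ids[r.integers(len(left_ids))]
            b = genes[r.choice(len(genes), p=pgene)]
            return a, b

        pairs = _sample_distinct_pairs(rng, n_edges, draw, seen)
        df = pd.DataFrame(pairs, columns=["source", "target"])
        df["source_type"] = left_type
        df["target_type"] = "gene"
        df["interaction_type"] = layer
        df["confidence"] = np.nan
        return df

    tf_gene = make_reg("tf_gene", tfs, "TF", budget["tf_gene"])
    mirna_gene = make_reg("mirna_gene", mirnas, "miRNA", budget["mirna_gene"])

    seen_tm = set()

    def draw_tm(r):
        return tfs[r.integers(len(tfs))], mirnas[r.integers(len(mirnas))]

    tm_pairs = _sample_distinct_pairs(rng, budget["tf_mirna"], draw_tm, seen_tm)
    tf_mirna = pd.DataFrame(tm_pairs, columns=["source", "target"])
    tf_mirna["source_type"] = "TF"
    tf_mirna["target_type"] = "miRNA"
    tf_mirna["interaction_type"] = "tf_mirna"
    tf_mirna["confidence"] = np.nan

    return {"tf_gene": tf_gene[_EDGE_COLUMNS], "mirna_gene": mirna_gene[_EDGE_COLUMNS],
            "tf_mirna": tf_mirna[_EDGE_COLUMNS], "ppi": ppi[_EDGE_COLUMNS]}


# --------------------------------------------------------------------------
# annotations: gene sets, diseases, compound reference profiles
# --------------------------------------------------------------------------

def _planted_annotations(config: SimulationConfig):
    """Ids of planted-enriched sets/diseases and reversal compounds."""
    ws = len(str(config.n_gene_sets))
    wd = len(str(config.n_diseases))
    wc = len(str(config.n_compounds))
    sets = {f"SET{i:0{ws}d}" for i in range(1, config.n_enriched_sets + 1)}
    dis = {f"D{i:0{wd}d}" for i in range(1, config.n_enriched_diseases + 1)}
    comp = {f"CPD{i:0{wc}d}" for i in range(1, config.n_reversal_compounds + 1)}
    return sets, dis, comp


def generate_annotations(config: SimulationConfig) -> tuple[
        dict[str, set[str]], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene sets (GMT-style dict), disease associations, category map, profiles.

    Planted-enriched gene sets and diseases are stacked with true
    differential features well above their random-expected share; planted
    reversal compounds rank the up-regulated planted features near the bottom
    of their reference profile and the down-regulated ones near the top, so a
    signature-reversal scorer should place them first.
    """
    config.validate()
    rng = config.rng("annotations")
    truth = _planted_de(config)
    proteins = config.protein_ids
    protein_set = set(proteins)
    de_prot_up = sorted(f for f, l in truth.items() if f in protein_set and l > 0)
    de_prot_dn = sorted(f for f, l in truth.items() if f in protein_set and l < 0)
    de_prot = de_prot_up + de_prot_dn
    enr_sets, enr_dis, rev_comp = _planted_annotations(config)

    # --- gene sets
    ws = len(str(config.n_gene_sets))
    gene_sets: dict[str, set[str]] = {}
    for i in range(1, config.n_gene_sets + 1):
        name = f"SET{i:0{ws}d}"
        size = int(rng.integers(10, 40))
        if name in enr_sets and de_prot:
            n_de = min(len(de_prot), max(3, int(round(0.6 * size))))
            members = set(rng.choice(de_prot, size=n_de, replace=False))
            pool = [p for p in proteins if p not in members]
            members |= set(rng.choice(pool, size=max(size - n_de, 0), replace=False))
        else:
            members = set(rng.choice(proteins, size=size, replace=False))
        gene_sets[name] = members

    # --- diseases and categories
    wd = len(str(config.n_diseases))
    wc2 = len(str(config.n_categories))
    molecules = config.feature_ids
    de_all = sorted(truth)
    rows = []
    for i in range(1, config.n_diseases + 1):
        did = f"D{i:0{wd}d}"
        size = int(rng.integers(10, 30))
        if did in enr_dis and de_all:
            n_de = min(len(de_all), max(3, int(round(0.5 * size))))
            assoc = set(rng.choice(de_all, size=n_de, replace=False))
            pool = [m for m in molecules if m not in assoc]
            assoc |= set(rng.choice(pool, size=max(size - n_de, 0), replace=False))
        else:
            assoc = set(rng.choice(molecules, size=size, replace=False))
        rows += [(m, did) for m in sorted(assoc)]
    assoc_df = pd.DataFrame(rows, columns=["molecule_id", "disease_id"])
    cats = [f"C{int(rng.integers(config.n_categories)) + 1:0{wc2}d}"
            for _ in range(config.n_diseases)]
    cat_map = pd.DataFrame({
        "disease_id": [f"D{i:0{wd}d}" for i in range(1, config.n_diseases + 1)],
        "category_id": cats,
    })

    # --- compound reference rank profiles over protein-coding features
    wcp = len(str(config.n_compounds))
    n_ref = len(proteins)
    prof_rows = []
    for i in range(1, config.n_compounds + 1):
        cid = f"CPD{i:0{wcp}d}"
        score = rng.normal(size=n_ref)
        if cid in rev_comp:
            idx = {p: j for j, p in enumerate(proteins)}
            for f in de_prot_up:
                score[idx[f]] -= 6.0   # pushed to the bottom: compound reverses
            for f in de_prot_dn:
                score[idx[f]] += 6.0   # pushed to the top
        order = np.argsort(-score, kind="stable")  # rank 1 = most up-regulated
        ranks = np.empty(n_ref, dtype=int)
        ranks[order] = np.arange(1, n_ref + 1)
        prof_rows += [(cid, proteins[j], int(ranks[j])) for j in range(n_ref)]
    profiles = pd.DataFrame(prof_rows, columns=["compound_id", "feature_id", "rank"])

    return gene_sets, assoc_df, cat_map, profiles


def generate_all(config: SimulationConfig):
    """All pipeline inputs plus the merged ground truth."""
    expr, gt = generate_expression(config)
    tables = generate_interactome(config)
    gene_sets, assoc, cat_map, profiles = generate_annotations(config)
    gt.planted_modules = _planted_cliques(config)
    gt.enriched_sets, gt.enriched_diseases, gt.reversal_compounds = _planted_annotations(config)
    return expr, tables, gene_sets, assoc, cat_map, profiles, gt
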