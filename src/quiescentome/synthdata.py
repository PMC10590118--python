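"""Synthetic data with the statistical structure of the macrophage study design.

The generator emulates a 2x2 factorial (lactoferrin treatment x LPS
stimulation) on four paired donors:

* gene model: ``y = baseline_g + donor_{g,d} + effect_{g,cond} + noise``,
  all on the log2 scale, with gene-specific donor random effects shared
  across a donor's four samples (paired design);
* two free planted axes: a treatment effect (applied to *both* hlf
  conditions, so the hlf vs hlf_LPS contrast is an exact null by
  construction) and an LPS response applied to the untreated condition only
  (emulating the observed abrogation of the LPS response under treatment);
* a planted hub-regulator module whose targets track the regulator's
  expression, for network-recovery tests;
* optional planted interaction edges with a closed-form expected
  propensity shift, for end-to-end checks of the interaction metric.

Every consumer-facing structure (annotations, gene sets, edge lists, partner
cell profiles) is produced here together with a ground-truth record.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CONDITIONS, CONTRASTS, ExpressionMatrix, GeneSetCollection, ValidationError, contrast_name, validate_edges

DEFAULT_CELL_TYPES = ("neutrophil", "NK_cell", "Treg", "mDC", "B_cell", "CD4_T")


class ConfigurationError(ValidationError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults mirror the modeled design
    (4 donors, 4 conditions, ~1/10-scale gene universe)."""

    n_genes: int = 2000
    n_donors: int = 4
    conditions: tuple = CONDITIONS
    #: planted DEG counts for the two free axes; the LPS-under-treatment
    #: contrast is their (disjoint) union and the hlf/hlf_LPS null is empty.
    n_de_per_contrast: dict = field(default_factory=lambda: {
        "hlf-vs-uM": 40, "uM_LPS-vs-uM": 97,
    })
    effect_size_range: tuple = (1.0, 3.5)
    donor_sd: float = 0.5
    noise_sd: float = 0.3
    baseline_mean_range: tuple = (4.0, 12.0)
    seed: int = 17

    # annotation classes (fractions of the gene universe; non-disjoint)
    class_fractions: dict = field(default_factory=lambda: {
        "cytokine": 0.10, "membrane": 0.20, "regulator": 0.08, "innate": 0.15,
    })

    # gene-set collection
    n_gene_sets: int = 30
    set_size_range: tuple = (10, 60)
    planted_overlap: float = 0.8

    # hub-regulator module (targets = regulator signal + module noise);
    # sized and powered to emulate a dominant regulator program driving the
    # treatment response, so it is the strongest co-expression module
    n_regulator_modules: int = 1
    module_size: int = 30
    module_noise_sd: float = 0.3

    # interaction network / partner cell profiles
    n_physical_edges: int = 80
    n_soluble_edges: int = 60
    cell_types: tuple = DEFAULT_CELL_TYPES
    expressed_fraction: float = 0.7
    n_planted_edges: int = 0
    planted_shift: float = 2.0
    planted_conditions: tuple = ("uM_LPS", "uM")
    planted_cell_type: str = DEFAULT_CELL_TYPES[0]

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_donors <= 0:
            raise ConfigurationError("n_genes and n_donors must be positive")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        lo, hi = self.effect_size_range
        if not (0.58 < lo <= hi):
            raise ConfigurationError(
                "effect sizes must lie outside [-0.58, 0.58] so planted DEG "
                "are detectable at the default cutoff")
        for name, frac in self.class_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"class fraction {name}={frac} outside [0, 1]")
        for c, n in self.n_de_per_contrast.items():
            if c not in ("hlf-vs-uM", "uM_LPS-vs-uM"):
                raise ConfigurationError(
                    f"plantable contrasts are hlf-vs-uM and uM_LPS-vs-uM, got {c!r}")
            if n < 0:
                raise ConfigurationError("planted DEG counts must be >= 0")
        total_planted = (sum(self.n_de_per_contrast.values())
                         + self.n_planted_edges)
        if total_planted > self.n_genes:
            raise ConfigurationError("more planted genes than the gene universe")
        if len(self.cell_types) < 5:
            raise ConfigurationError("need >= 5 partner cell types")
        if self.n_planted_edges and not set(self.planted_conditions) <= {"uM", "uM_LPS"}:
            raise ConfigurationError(
                "planted interaction shifts must target uM/uM_LPS to preserve "
                "the hlf == hlf_LPS identity")
        if self.n_planted_edges and self.planted_cell_type not in self.cell_types:
            raise ConfigurationError("planted_cell_type must be a listed cell type")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    table: pd.DataFrame                       # gene, contrast, true_logFC, is_de
    effects: pd.DataFrame                     # gene x condition effect matrix
    regulator_modules: dict                   # regulator -> list of targets
    planted_gene_sets: dict = field(default_factory=dict)   # set name -> contrast
    planted_edge_truth: dict | None = None

    def de_genes(self, contrast: str) -> set:
        t = self.table
        return set(t.loc[(t["contrast"] == contrast) & t["is_de"], "gene"])


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


def generate_expression(config: SimConfig) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Draw one dataset from the generative model; reproducible given the seed."""
    rng = np.random.default_rng([config.seed, 0])
    genes = _gene_names(config.n_genes)
    n_cond = len(config.conditions)
    donors = [f"D{i + 1}" for i in range(config.n_donors)]

    # --- planted structure: disjoint gene blocks ------------------------------
    n_hlf = config.n_de_per_contrast.get("hlf-vs-uM", 0)
    n_lps = config.n_de_per_contrast.get("uM_LPS-vs-uM", 0)
    perm = rng.permutation(config.n_genes)
    hlf_idx = perm[:n_hlf]
    lps_idx = perm[n_hlf:n_hlf + n_lps]
    shift_idx = perm[n_hlf + n_lps:n_hlf + n_lps + config.n_planted_edges]

    lo, hi = config.effect_size_range
    signs = rng.choice([-1.0, 1.0], size=config.n_genes)
    magnitudes = rng.uniform(lo, hi, size=config.n_genes)

    effects = pd.DataFrame(0.0, index=genes, columns=list(config.conditions))
    for i in hlf_idx:
        e = signs[i] * magnitudes[i]
        effects.iloc[i, effects.columns.get_loc("hlf")] = e
        effects.iloc[i, effects.columns.get_loc("hlf_LPS")] = e
    for i in lps_idx:
        e = signs[i] * magnitudes[i]
        effects.iloc[i, effects.columns.get_loc("uM_LPS")] = e
    shift_cond = config.planted_conditions[0]
    for i in shift_idx:
        effects.iloc[i, effects.columns.get_loc(shift_cond)] = config.planted_shift

    # --- hub-regulator modules (members drawn from the treatment-DE block) ---
    modules: dict[str, list[str]] = {}
    module_member_idx: set[int] = set()
    if config.n_regulator_modules > 0:
        need = config.n_regulator_modules * (config.module_size + 1)
        if need > n_hlf:
            raise ConfigurationError(
                "regulator modules need at least n_modules*(module_size+1) "
                "planted treatment DEG")
        pool = list(hlf_idx)
        pos = 0
        for _ in range(config.n_regulator_modules):
            reg_i = pool[pos]
            tgt_i = pool[pos + 1:pos + 1 + config.module_size]
            pos += config.module_size + 1
            modules[genes[reg_i]] = [genes[j] for j in tgt_i]
            module_member_idx.update([reg_i, *tgt_i])
            # the planted hub drives a strong program: its effect sits at the
            # top of the range, and targets share its condition-effect vector
            reg_effect = signs[reg_i] * hi
            effects.iloc[reg_i, effects.columns.get_loc("hlf")] = reg_effect
            effects.iloc[reg_i, effects.columns.get_loc("hlf_LPS")] = reg_effect
            effects.iloc[tgt_i] = np.tile(effects.iloc[reg_i].to_numpy(),
                                          (len(tgt_i), 1))

    # --- assemble the matrix --------------------------------------------------
    baseline = rng.uniform(*config.baseline_mean_range, size=config.n_genes)
    donor_eff = rng.normal(0.0, config.donor_sd,
                           size=(config.n_genes, config.n_donors))
    noise = rng.normal(0.0, config.noise_sd,
                       size=(config.n_genes, config.n_donors * n_cond))

    sample_ids, cond_of, donor_of = [], [], []
    for d in donors:
        for c in config.conditions:
            sample_ids.append(f"{d}_{c}")
            cond_of.append(c)
            donor_of.append(d)

    eff_arr = effects.to_numpy()
    cond_index = {c: k for k, c in enumerate(config.conditions)}
    mat = np.empty((config.n_genes, len(sample_ids)))
    for s, (c, d) in enumerate(zip(cond_of, donor_of)):
        di = donors.index(d)
        mat[:, s] = (baseline + donor_eff[:, di]
                     + eff_arr[:, cond_index[c]] + noise[:, s])

    # module targets: the regulator's shared signal (donor effect + exact
    # condition effect + condition-centred noise) plus independent noise, so
    # each target's population logFC equals the recorded truth while the
    # module stays strongly co-expressed
    cond_arr = np.array(cond_of)
    for reg, targets in modules.items():
        ri = genes.index(reg)
        reg_noise = noise[ri].copy()
        for c in config.conditions:
            sel = cond_arr == c
            reg_noise[sel] -= reg_noise[sel].mean()
        shared = mat[ri] - baseline[ri] - noise[ri] + reg_noise
        for t in targets:
            ti = genes.index(t)
            mat[ti] = (baseline[ti] + shared
                       + rng.normal(0.0, config.module_noise_sd, size=mat.shape[1]))

    values = pd.DataFrame(mat, index=pd.Index(genes, name="gene"),
                          columns=sample_ids)
    samples = pd.DataFrame({"condition": cond_of, "donor": donor_of},
                           index=pd.Index(sample_ids, name="sample"))
    expr = ExpressionMatrix(values, samples)

    rows = []
    for num, den in CONTRASTS:
        lfc = eff_arr[:, cond_index[num]] - eff_arr[:, cond_index[den]]
        for i, g in enumerate(genes):
            rows.append((g, contrast_name(num, den), lfc[i], lfc[i] != 0.0))
    truth_table = pd.DataFrame(rows, columns=["gene", "contrast", "true_logFC", "is_de"])

    planted_edge_truth = None
    if config.n_planted_edges:
        n_ct = len(config.cell_types)
        planted_edge_truth = {
            "channel": "soluble",
            "cell_type": config.planted_cell_type,
            "conditions": tuple(config.planted_conditions),
            "macro_genes": [genes[i] for i in shift_idx],
            "n_edges": int(config.n_planted_edges),
            # post-standardization: one-hot across 4 conditions gives a macro
            # z-difference of 2; one-hot across n_ct cell types gives a
            # partner z of (n_ct - 1)/sqrt(n_ct)  (ddof=1 z-scores)
            "delta_per_edge": 2.0 * (n_ct - 1) / np.sqrt(n_ct),
            "expected_delta": config.n_planted_edges * 2.0 * (n_ct - 1) / np.sqrt(n_ct),
        }

    truth = SimulationTruth(
        table=truth_table, effects=effects, regulator_modules=modules,
        planted_edge_truth=planted_edge_truth,
    )
    return expr, truth


def generate_annotations(config: SimConfig, expr: ExpressionMatrix,
                         truth: SimulationTruth | None = None) -> pd.DataFrame:
    """Assign genes to (non-disjoint) annotation classes.

    Module regulators are guaranteed the ``regulator`` class and planted
    interaction genes the ``cytokine`` class, so downstream stages see them.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = list(expr.genes)
    rows = []
    forced = {"regulator": set(), "cytokine": set()}
    if truth is not None:
        forced["regulator"] |= set(truth.regulator_modules)
        if truth.planted_edge_truth:
            forced["cytokine"] |= set(truth.planted_edge_truth["macro_genes"])
    for cls, frac in sorted(config.class_fractions.items()):
        n = int(round(frac * len(genes)))
        chosen = set(rng.choice(genes, size=n, replace=False)) if n else set()
        chosen |= forced.get(cls, set())
        rows.extend((g, cls) for g in sorted(chosen))
    ann = pd.DataFrame(rows, columns=["gene", "class"])
    return ann.reset_index(drop=True)


def validate_annotations(ann: pd.DataFrame, genes) -> pd.DataFrame:
    universe = set(genes)
    missing = set(ann["gene"]) - universe
    if missing:
        raise ValidationError(
            f"annotated gene(s) absent from expression: {sorted(missing)[:5]}")
    if ann.duplicated(["gene", "class"]).any():
        raise ValidationError("duplicate (gene, class) annotation rows")
    return ann


def generate_genesets(config: SimConfig, truth: SimulationTruth,
                      genes) -> GeneSetCollection:
    """Pathway-like sets: one planted per free contrast axis, rest uniform."""
    rng = np.random.default_rng([config.seed, 2])
    genes = list(genes)
    lo, hi = config.set_size_range
    if hi > len(genes):
        raise ConfigurationError("set size range exceeds the gene universe")
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    truth.planted_gene_sets = {}
    for contrast in sorted(config.n_de_per_contrast):
        deg = sorted(truth.de_genes(contrast))
        if not deg:
            continue
        size = int(rng.integers(lo, hi + 1))
        n_deg = min(len(deg), max(1, int(round(config.planted_overlap * size))))
        members = set(rng.choice(deg, size=n_deg, replace=False))
        non_de = [g for g in genes if g not in set(deg)]
        fill = size - len(members)
        if fill > 0:
            members |= set(rng.choice(non_de, size=fill, replace=False))
        name = f"PLANTED_{contrast}"
        sets[name] = members
        descriptions[name] = f"planted: enriched for {contrast} DEG"
        truth.planted_gene_sets[name] = contrast
    n_random = config.n_gene_sets - len(sets)
    for i in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        name = f"RANDOM_{i + 1:03d}"
        sets[name] = set(rng.choice(genes, size=size, replace=False))
        descriptions[name] = "uniform random set"
    return GeneSetCollection(sets, descriptions)


def generate_interactions(config: SimConfig, ann: pd.DataFrame,
                          expr: ExpressionMatrix, truth: SimulationTruth,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list (physical PPI + directed cytokine->receptor) and partner
    cell-type expression profiles, with optional planted propensity shifts."""
    rng = np.random.default_rng([config.seed, 3])
    membrane = sorted(ann.loc[ann["class"] == "membrane", "gene"])
    cytokines = sorted(ann.loc[ann["class"] == "cytokine", "gene"])

    edges = []
    seen = set()
    if config.n_physical_edges:
        if len(membrane) < 2:
            raise ConfigurationError("physical edges need >= 2 membrane genes")
        attempts = 0
        while len([e for e in edges if e[2] == "physical"]) < config.n_physical_edges:
            a, b = rng.choice(membrane, size=2, replace=False)
            key = (min(a, b), max(a, b))
            attempts += 1
            if key in seen:
                if attempts > 50 * config.n_physical_edges:
                    break
                continue
            seen.add(key)
            edges.append((a, b, "physical", 0, round(float(rng.uniform(0.4, 1.0)), 3)))

    receptors = [f"REC{i + 1:03d}" for i in range(config.n_soluble_edges)]
    for rec in receptors:
        cyt = str(rng.choice(cytokines)) if cytokines else None
        if cyt is None:
            raise ConfigurationError("soluble edges need cytokine-class genes")
        edges.append((cyt, rec, "soluble", 1, round(float(rng.uniform(0.4, 1.0)), 3)))

    planted_partners = []
    if config.n_planted_edges:
        pet = truth.planted_edge_truth
        planted_partners = [f"PREC{i + 1:02d}" for i in range(config.n_planted_edges)]
        for g, rec in zip(pet["macro_genes"], planted_partners):
            edges.append((g, rec, "soluble", 1, 0.95))
        pet["edges"] = list(zip(pet["macro_genes"], planted_partners))

    edge_df = validate_edges(pd.DataFrame(
        edges, columns=["gene_a", "gene_b", "channel", "directed", "confidence"]))

    profile_genes = sorted(set(membrane) | set(cytokines) | set(receptors))
    n_ct = len(config.cell_types)
    expressed = rng.random((len(profile_genes), n_ct)) < config.expressed_fraction
    levels = rng.uniform(1.0, 10.0, size=(len(profile_genes), n_ct))
    prof = np.where(expressed, levels, 0.0)
    profiles = pd.DataFrame(prof, index=pd.Index(profile_genes, name="gene"),
                            columns=list(config.cell_types))
    if planted_partners:
        t_col = config.planted_cell_type
        one_hot = pd.DataFrame(0.0, index=pd.Index(planted_partners, name="gene"),
                               columns=list(config.cell_types))
        one_hot[t_col] = 8.0
        profiles = pd.concat([profiles, one_hot])
    return edge_df, profiles


@dataclass
class SimulatedStudy:
    """Bundle of everything one simulation produces."""

    config: SimConfig
    expression: ExpressionMatrix
    truth: SimulationTruth
    annotations: pd.DataFrame
    gene_sets: GeneSetCollection
    edges: pd.DataFrame
    cell_profiles: pd.DataFrame


def simulate(config: SimConfig | None = None) -> SimulatedStudy:
    """Generate a full synthetic study (expression, truth, annotations,
    gene sets, interaction network, partner profiles)."""
    config = config or SimConfig()
    expr, truth = generate_expression(config)
    ann = generate_annotations(config, expr, truth)
    sets = generate_genesets(config, truth, expr.genes)
    edges, profiles = generate_interactions(config, ann, expr, truth)
    return SimulatedStudy(config, expr, truth, ann, sets, edges, profiles)
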