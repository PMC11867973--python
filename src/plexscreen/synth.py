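"""Synthetic 96-plex hashed drug-screen data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: one 96-well plate per model, negative-binomial UMI counts with
MOA-specific planted log2 fold-change modules, dual-HTO tag counts with a
signal/background/ambient decomposition, hashing doublets and negative
(unlabeled) cells, per-model mitochondrial fractions, and four-parameter
logistic dose-response truths for the drug library.  Every retained cell
carries exactly one truth record so downstream stages can be scored
against known labels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (ConfigError, CountMatrixHandle, GeneSetCollection, PlateMap,
                 PLATE_MAP_COLUMNS, ValidationError, log_stage)
from .doseresponse import FourPL

DEFAULT_MODELS = ("JHOS2", "PDC2", "PDC3")
DEFAULT_CONCENTRATIONS = (1.0, 10.0, 100.0, 1000.0, 10000.0)


@dataclass
class SimConfig:
    """Study-design parameters for the hashed-experiment simulator.

    Defaults mirror the screen design being emulated: a 96-well plate per
    model (45 drugs from 13 MOAs plus DMSO control, treatments in duplicate
    with 4 extra control wells), ~130 target cells per well, 2,000 genes.
    """

    model_names: tuple = DEFAULT_MODELS
    n_drugs: int = 45
    n_moas: int = 13
    n_replicates: int = 2
    n_extra_controls: int = 4
    n_row_tags: int = 8
    n_col_tags: int = 12
    target_cells_per_well: float = 130.0
    cell_count_dispersion: float = 20.0      # NB size of per-well cell counts
    n_genes: int = 2000
    baseline_log_mean: float = 1.0           # log-normal gene baseline means
    baseline_log_sigma: float = 1.2
    libsize_log_sigma: float = 0.35          # per-cell library-size factor
    gene_nb_size: float = 10.0               # shared NB size for gene counts
    module_size: int = 40                    # planted genes per MOA
    planted_log2fc: float = 2.0
    hto_signal_mean: float = 200.0           # mu_s
    hto_background_mean: float = 5.0         # mu_b
    hto_nb_size: float = 8.0                 # r_h
    doublet_rate: float = 0.05
    negative_rate: float = 0.05
    ambient_rate: float = 1.0                # Poisson add-on to all tags
    mito_gene_fraction: float = 0.01
    mito_pct_mean: dict = field(default_factory=lambda: {
        "JHOS2": 8.0, "PDC2": 10.0, "PDC3": 6.0})
    mito_pct_concentration: float = 60.0     # Beta concentration of per-cell mito%
    seed: int = 0

    def __post_init__(self):
        for name in ("doublet_rate", "negative_rate", "mito_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not self.hto_signal_mean > self.hto_background_mean >= 0.0:
            raise ConfigError("need hto_signal_mean > hto_background_mean >= 0")
        n_module_genes = self.n_moas * self.module_size
        n_mito = int(round(self.mito_gene_fraction * self.n_genes))
        if n_module_genes + n_mito > self.n_genes:
            raise ConfigError(
                f"{n_module_genes} module genes + {n_mito} mitochondrial genes "
                f"exceed n_genes={self.n_genes}")
        unknown = set(self.model_names) - set(self.mito_pct_mean)
        if unknown:
            raise ConfigError(f"no mito_pct_mean for models {sorted(unknown)}")

    @property
    def n_wells(self) -> int:
        return self.n_row_tags * self.n_col_tags

    @property
    def n_treatments(self) -> int:
        return self.n_drugs + 1  # drugs + control


@dataclass
class ExperimentDesign:
    """Gene-level truths shared across plates."""

    gene_ids: list
    baseline_means: np.ndarray                 # (G,)
    moa_log2fc: dict                           # moa -> (G,) planted log2FC
    mito_gene_ids: list
    drug_moa: dict                             # drug -> moa
    fourpl_truths: dict                        # drug -> FourPL

    def log2fc_table(self) -> pd.DataFrame:
        rows = []
        for moa, lfc in self.moa_log2fc.items():
            for i in np.flatnonzero(lfc):
                rows.append({"moa": moa, "gene": self.gene_ids[i],
                             "log2fc": float(lfc[i])})
        return pd.DataFrame(rows, columns=["moa", "gene", "log2fc"])


@dataclass
class PlateSim:
    model: str
    gene_counts: CountMatrixHandle
    tag_counts: CountMatrixHandle
    plate_map: PlateMap
    truth: pd.DataFrame                        # one record per droplet


@dataclass
class HashedExperiment:
    config: SimConfig
    design: ExperimentDesign
    plates: dict                               # model -> PlateSim

    @property
    def truth(self) -> pd.DataFrame:
        return pd.concat([p.truth for p in self.plates.values()],
                         ignore_index=True)


def _well_ids(n_rows: int, n_cols: int) -> list:
    return [f"{chr(ord('A') + r)}{c + 1:02d}"
            for r in range(n_rows) for c in range(n_cols)]


def build_plate_map(model: str, config: SimConfig) -> PlateMap:
    """Deterministic plate layout: 46 treatments in duplicate + extra controls.

    Wells are filled in row-major order (A01..H12); the first pass holds
    replicate 1 of every treatment, the second pass replicate 2, and the
    remaining wells additional DMSO control replicates.
    """
    row_tags = [f"R{i}" for i in range(1, config.n_row_tags + 1)]
    col_tags = [f"C{i}" for i in range(1, config.n_col_tags + 1)]
    wells = _well_ids(config.n_row_tags, config.n_col_tags)
    drugs = [f"drug{i:02d}" for i in range(1, config.n_drugs + 1)]
    moas = {d: f"MOA{(i % config.n_moas) + 1:02d}" for i, d in enumerate(drugs)}
    treatments = drugs + ["DMSO"]

    records = []
    control_rep = 0
    for w_idx, well in enumerate(wells):
        r, c = divmod(w_idx, config.n_col_tags)
        t_idx, rep = w_idx % len(treatments), w_idx // len(treatments) + 1
        if w_idx < config.n_replicates * len(treatments):
            drug = treatments[t_idx]
        else:
            drug = "DMSO"
        if drug == "DMSO":
            control_rep += 1
            rep = control_rep
        is_control = drug == "DMSO"
        records.append({
            "well": well, "row_tag": row_tags[r], "col_tag": col_tags[c],
            "model": model, "drug": drug,
            "moa": "control" if is_control else moas[drug],
            "concentration": 0.0 if is_control else 1000.0, "unit": "nM",
            "replicate": rep, "is_control": is_control,
        })
    return PlateMap(pd.DataFrame(records, columns=PLATE_MAP_COLUMNS))


def build_design(config: SimConfig, rng: np.random.Generator) -> ExperimentDesign:
    G = config.n_genes
    n_mito = int(round(config.mito_gene_fraction * G))
    n_module = config.n_moas * config.module_size
    gene_ids = [f"GENE{i + 1:05d}" for i in range(G - n_mito)]
    gene_ids += [f"MT-GENE{i + 1:02d}" for i in range(n_mito)]

    baseline = rng.lognormal(config.baseline_log_mean,
                             config.baseline_log_sigma, size=G)

    drugs = [f"drug{i:02d}" for i in range(1, config.n_drugs + 1)]
    drug_moa = {d: f"MOA{(i % config.n_moas) + 1:02d}" for i, d in enumerate(drugs)}
    drug_moa["DMSO"] = "control"

    # MOA m owns a disjoint block of module_size non-mitochondrial genes;
    # the first half is planted up, the second half down.
    moa_log2fc = {}
    for m in range(config.n_moas):
        lfc = np.zeros(G)
        lo = m * config.module_size
        block = np.arange(lo, lo + config.module_size)
        half = config.module_size // 2
        lfc[block[:half]] = config.planted_log2fc
        lfc[block[half:]] = -config.planted_log2fc
        moa_log2fc[f"MOA{m + 1:02d}"] = lfc
    moa_log2fc["control"] = np.zeros(G)

    fourpl = sample_fourpl_truths(drugs, rng)
    return ExperimentDesign(gene_ids, baseline, moa_log2fc,
                            gene_ids[G - n_mito:], drug_moa, fourpl)


def sample_fourpl_truths(drugs, rng: np.random.Generator,
                         concentrations=DEFAULT_CONCENTRATIONS) -> dict:
    """Draw realistic 4PL truths with midpoints inside the tested range."""
    lo, hi = np.log10(concentrations[0]), np.log10(concentrations[-1])
    truths = {}
    for drug in drugs:
        truths[drug] = FourPL(
            bottom=float(rng.uniform(0.0, 5.0)),
            top=float(rng.uniform(30.0, 100.0)),
            log_ec50=float(rng.uniform(lo + 0.5, hi - 0.5)),
            hill=float(rng.uniform(0.7, 2.0)),
        )
    return truths


def _nb_draw(rng, mean, size):
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


def generate_plate(model: str, config: SimConfig, design: ExperimentDesign,
                   rng: np.random.Generator) -> PlateSim:
    """Simulate one hashed 96-well plate for a single model."""
    plate_map = build_plate_map(model, config)
    G = config.n_genes
    n_mito = len(design.mito_gene_ids)
    mito_idx = np.arange(G - n_mito, G)
    nonmito_idx = np.arange(G - n_mito)
    row_tags = [f"R{i}" for i in range(1, config.n_row_tags + 1)]
    col_tags = [f"C{i}" for i in range(1, config.n_col_tags + 1)]
    tag_ids = row_tags + col_tags
    n_tags = len(tag_ids)
    mito_mean = float(np.clip(config.mito_pct_mean[model], 0.1, 99.0)) / 100.0
    conc = config.mito_pct_concentration

    gene_blocks, tag_blocks = [], []
    truth_records = []
    for _, well in plate_map.wells.iterrows():
        n_cells = int(rng.negative_binomial(
            config.cell_count_dispersion,
            config.cell_count_dispersion /
            (config.cell_count_dispersion + config.target_cells_per_well)))
        n_cells = max(n_cells, 1)
        lfc = design.moa_log2fc[well["moa"]]
        well_means = design.baseline_means * np.exp2(lfc)

        lib = rng.lognormal(-config.libsize_log_sigma ** 2 / 2.0,
                            config.libsize_log_sigma, size=n_cells)
        mu = lib[:, None] * well_means[None, :]
        if n_mito:
            # rescale mitochondrial means so each cell hits its drawn mito
            # fraction while the non-mito total is preserved
            f = rng.beta(mito_mean * conc, (1.0 - mito_mean) * conc, size=n_cells)
            s_nm = mu[:, nonmito_idx].sum(axis=1)
            s_mt = mu[:, mito_idx].sum(axis=1)
            k = f * s_nm / ((1.0 - f) * np.maximum(s_mt, 1e-12))
            mu[:, mito_idx] *= k[:, None]
        counts = _nb_draw(rng, mu, config.gene_nb_size)

        tag_mu = np.full((n_cells, n_tags), config.hto_background_mean)
        r_idx = tag_ids.index(well["row_tag"])
        c_idx = tag_ids.index(well["col_tag"])
        tag_mu[:, [r_idx, c_idx]] = config.hto_signal_mean
        tags = _nb_draw(rng, tag_mu, config.hto_nb_size)

        gene_blocks.append(counts)
        tag_blocks.append(tags)
        for _ in range(n_cells):
            truth_records.append((well["well"], well["drug"], well["moa"]))

    genes = np.concatenate(gene_blocks, axis=0)       # cells x G
    tags = np.concatenate(tag_blocks, axis=0)         # cells x T
    n = genes.shape[0]
    truth = pd.DataFrame(truth_records, columns=["well", "drug", "moa"])
    truth.insert(0, "model", model)
    truth["cell_class"] = "singlet"

    # negatives: labeling failed, tags are background-only
    n_neg = int(round(config.negative_rate * n))
    order = rng.permutation(n)
    neg_idx = order[:n_neg]
    if n_neg:
        neg_mu = np.full((n_neg, n_tags), config.hto_background_mean)
        tags[neg_idx] = _nb_draw(rng, neg_mu, config.hto_nb_size)
        truth.loc[neg_idx, "cell_class"] = "negative"

    # doublets: merge random pairs of droplets (gene and tag counts add)
    n_doub = int(round(config.doublet_rate * n))
    doub_pool = order[n_neg:n_neg + 2 * n_doub]
    keep_mask = np.ones(n, dtype=bool)
    for i in range(n_doub):
        a, b = doub_pool[2 * i], doub_pool[2 * i + 1]
        genes[a] += genes[b]
        tags[a] += tags[b]
        keep_mask[b] = False
        truth.loc[a, "cell_class"] = "doublet"
        if truth.loc[a, "well"] != truth.loc[b, "well"]:
            truth.loc[a, ["well", "drug", "moa"]] = ["", "", ""]

    if config.ambient_rate > 0:
        tags += rng.poisson(config.ambient_rate, size=tags.shape)

    genes = genes[keep_mask]
    tags = tags[keep_mask]
    truth = truth.loc[keep_mask].reset_index(drop=True)
    barcodes = [f"{model}_BC{i + 1:06d}" for i in range(genes.shape[0])]
    truth.insert(1, "barcode", barcodes)

    gene_handle = CountMatrixHandle(sp.csr_matrix(genes.T), design.gene_ids, barcodes)
    tag_handle = CountMatrixHandle(sp.csr_matrix(tags.T), tag_ids, barcodes)
    log_stage("simulate", model=model, droplets=len(barcodes),
              singlets=int((truth["cell_class"] == "singlet").sum()))
    return PlateSim(model, gene_handle, tag_handle, plate_map, truth)


def generate_hashed_experiment(config: SimConfig) -> HashedExperiment:
    """Simulate one plate per model; same seed gives identical output."""
    rng = np.random.default_rng(config.seed)
    design = build_design(config, rng)
    plates = {}
    for model in config.model_names:
        plates[model] = generate_plate(model, config, design, rng)
    return HashedExperiment(config, design, plates)


# ---------------------------------------------------------------------------
# Dose-response panels
# ---------------------------------------------------------------------------

def generate_dose_response(drugs, fourpl_truths: dict, noise_sd: float = 5.0,
                           seed: int = 0, samples=("S1",),
                           concentrations=DEFAULT_CONCENTRATIONS) -> pd.DataFrame:
    """Five-point % inhibition panels over a 10,000-fold concentration range.

    Responses are the drug's 4PL curve plus Gaussian noise, clipped to
    [-10, 110] to mimic plate-reader normalization artifacts.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.size != 5:
        raise ValidationError(f"expected 5 concentrations, got {conc.size}")
    if np.any(np.diff(conc) <= 0):
        raise ValidationError("concentration grid must be strictly increasing")
    span = np.log10(conc[-1] / conc[0])
    if abs(span - 4.0) > 1e-9:
        raise ValidationError(
            f"concentrations must span exactly 4 log10 units, got {span:.3f}")
    rng = np.random.default_rng(seed)
    rows = []
    x = np.log10(conc)
    for sample in samples:
        for drug in drugs:
            curve = fourpl_truths[drug]
            y = curve(x) + rng.normal(0.0, noise_sd, size=x.size)
            y = np.clip(y, -10.0, 110.0)
            for c, v in zip(conc, y):
                rows.append({"sample": sample, "drug": drug,
                             "concentration": c, "inhibition": float(v)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Perturbation-signature corpus
# ---------------------------------------------------------------------------

def generate_lincs_corpus(n_experiments: int, moas, tissues, timepoints,
                          set_size: int = 250, planted_genes: dict | None = None,
                          n_universe: int = 3000, seed: int = 0):
    """Synthetic perturbation-signature corpus: metadata plus up/down sets.

    ``planted_genes`` maps gene symbol -> (moa, probability); a planted gene
    is inserted into the up set of each experiment with a matching MOA with
    the stated probability.  Every experiment carries exactly ``set_size``
    up genes and ``set_size`` down genes.
    """
    moas, tissues, timepoints = list(moas), list(tissues), list(timepoints)
    if not moas or not tissues:
        raise ValidationError("moas and tissues must be nonempty")
    if set_size > n_universe:
        raise ValidationError(f"set_size={set_size} exceeds universe {n_universe}")
    planted_genes = {str(g).upper(): (m, p)
                     for g, (m, p) in (planted_genes or {}).items()}
    universe = [f"LG{i + 1:05d}" for i in range(n_universe)]
    universe = [g for g in universe if g not in planted_genes]
    universe += list(planted_genes)
    universe = sorted(set(universe))
    rng = np.random.default_rng(seed)

    meta_rows, up_sets, down_sets = [], {}, {}
    for i in range(n_experiments):
        exp_id = f"EXP{i + 1:05d}"
        moa = moas[rng.integers(len(moas))]
        tissue = tissues[rng.integers(len(tissues))]
        timepoint = timepoints[rng.integers(len(timepoints))]
        meta_rows.append({"experiment_id": exp_id, "moa": moa,
                          "tissue": tissue, "timepoint": timepoint})
        planted = [g for g, (m, p) in planted_genes.items()
                   if m == moa and rng.random() < p]
        rest = [g for g in universe if g not in planted]
        fill = rng.choice(len(rest), size=set_size - len(planted), replace=False)
        up = planted + [rest[j] for j in fill]
        not_up = [g for g in universe if g not in set(up)]
        down_pick = rng.choice(len(not_up), size=set_size, replace=False)
        down = [not_up[j] for j in down_pick]
        up_sets[exp_id] = up
        down_sets[exp_id] = down

    metadata = pd.DataFrame(meta_rows)
    return (metadata,
            GeneSetCollection(up_sets),
            GeneSetCollection(down_sets))
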