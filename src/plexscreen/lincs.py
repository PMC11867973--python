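"""Perturbation-signature corpus filtering and occurrence counting.

Experiments from an L1000-style corpus (each summarized by a top-k
upregulated and a top-k downregulated gene set) are filtered by
perturbagen mechanism of action, tissue of origin and treatment
timepoint; for a user-supplied universe of pathway signature genes, the
number of filtered experiments whose up (resp. down) set contains each
gene is counted, yielding the waterfall of most commonly perturbed
genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import FormatError, GeneSetCollection, ValidationError, log_stage

REQUIRED_COLUMNS = ("moa", "tissue", "timepoint")


@dataclass
class LincsFilter:
    """Inclusion criteria; all three must hold for an experiment."""

    moas: frozenset = frozenset({"AKT inhibitor", "PI3K inhibitor"})
    tissues: frozenset = frozenset({"ovary", "breast"})
    timepoints: frozenset = frozenset({24, 48, 72, 96, 120})

    def __post_init__(self):
        if not (self.moas and self.tissues and self.timepoints):
            raise ValidationError("filter sets must all be nonempty")
        object.__setattr__(self, "moas", frozenset(self.moas))
        object.__setattr__(self, "tissues", frozenset(self.tissues))
        object.__setattr__(self, "timepoints", frozenset(self.timepoints))


def filter_experiments(metadata: pd.DataFrame,
                       filt: LincsFilter | None = None) -> list:
    """Experiment ids satisfying MOA, tissue and timepoint criteria.

    MOA and tissue match exactly after case-folding; timepoints match
    numerically (hours).
    """
    filt = filt or LincsFilter()
    missing = set(REQUIRED_COLUMNS) - set(metadata.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    id_col = "experiment_id" if "experiment_id" in metadata.columns else None
    moas = {m.casefold() for m in filt.moas}
    tissues = {t.casefold() for t in filt.tissues}
    timepoints = {float(t) for t in filt.timepoints}

    mask = (metadata["moa"].astype(str).str.casefold().isin(moas)
            & metadata["tissue"].astype(str).str.casefold().isin(tissues)
            & metadata["timepoint"].astype(float).isin(timepoints))
    if id_col:
        ids = metadata.loc[mask, id_col].tolist()
    else:
        ids = metadata.index[mask].tolist()
    log_stage("lincs_filter", experiments=len(metadata), kept=len(ids))
    return ids


def occurrence_counts(experiment_ids, up_sets: GeneSetCollection,
                      down_sets: GeneSetCollection,
                      signature_genes) -> pd.DataFrame:
    """Per-gene counts of occurrence in up and down sets (waterfall order).

    Every filtered experiment must have both an up and a down set; counts
    are restricted to ``signature_genes`` and the result is sorted by
    up_count - down_count, descending (the plotted value is up_count for
    the positive arm and -down_count for the negative arm).
    """
    experiment_ids = list(experiment_ids)
    missing = [e for e in experiment_ids
               if e not in up_sets or e not in down_sets]
    if missing:
        raise ValidationError(
            f"experiments missing an up or down set: {missing[:10]}")
    signature = sorted({str(g).upper() for g in signature_genes})
    up_count = {g: 0 for g in signature}
    down_count = {g: 0 for g in signature}
    for exp in experiment_ids:
        for g in set(up_sets[exp]) & set(signature):
            up_count[g] += 1
        for g in set(down_sets[exp]) & set(signature):
            down_count[g] += 1
    df = pd.DataFrame({
        "gene": signature,
        "up_count": [up_count[g] for g in signature],
        "down_count": [down_count[g] for g in signature],
    })
    df["signed_count"] = df["up_count"] - df["down_count"]
    df = df.sort_values(["signed_count", "gene"],
                        ascending=[False, True], kind="stable")
    return df.reset_index(drop=True)
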