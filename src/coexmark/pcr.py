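"""ΔΔCt quantification of qPCR cycle-threshold tables.

Relative expression is computed by the comparative CT method against a
reference transcript and a control-group calibrator:

    ΔCt  = CT_gene − CT_reference               (per sample, cycles)
    ΔΔCt = ΔCt − mean(ΔCt over control samples) (per gene, cycles)
    RQ   = 2^(−ΔΔCt)                            (fold change, dimensionless)

The calibrator is the arithmetic mean ΔCt of the control group (a
population calibrator rather than a single sample), so the control-group
mean ΔΔCt is exactly zero per gene by construction. Amplification
efficiency is fixed at perfect doubling, which the 2^(−ΔΔCt) form assumes.
Censored reactions (CT at the run limit, typically 40 cycles) keep their
value — a conservative floor on expression — and carry a flag so callers
can exclude them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datasets import CONTROL, CtTable


class NormalizedExpression:
    """Long-format ΔΔCt output with matrix accessors."""

    def __init__(self, table: pd.DataFrame, reference_gene: str,
                 labels: pd.Series) -> None:
        #: columns: sample, gene, ct, dct, ddct, rq, censored
        self.table = table
        self.reference_gene = reference_gene
        self.labels = labels

    def matrix(self, column: str = "rq") -> pd.DataFrame:
        """Genes × samples matrix of one derived quantity."""
        return self.table.pivot(index="gene", columns="sample", values=column)

    def censored_matrix(self) -> pd.DataFrame:
        return self.table.pivot(index="gene", columns="sample", values="censored")

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def delta_delta_ct(ct: CtTable) -> NormalizedExpression:
    """Normalize a CT table to reference gene and control-group calibrator.

    Samples lacking a reference-gene CT are dropped with a warning; at
    least one control sample is required to form the calibrator.
    """
    ref = ct.ct.loc[ct.reference_gene]
    usable = ref.notna()
    if not usable.all():
        dropped = ref.index[~usable].tolist()
        warnings.warn(f"samples without reference CT dropped: {dropped}",
                      stacklevel=2)
    samples = ref.index[usable]
    labels = ct.labels.loc[samples]
    controls = labels.index[labels == CONTROL]
    if len(controls) == 0:
        raise ValueError("no control samples: cannot form the calibrator")

    genes = [g for g in ct.genes if g != ct.reference_gene]
    ct_vals = ct.ct.loc[genes, samples]
    dct = ct_vals.sub(ref.loc[samples], axis=1)
    calibrator = dct.loc[:, controls].mean(axis=1)
    ddct = dct.sub(calibrator, axis=0)
    rq = np.power(2.0, -ddct)
    censored = ct_vals >= ct.max_cycles

    long = pd.DataFrame({
        "sample": np.tile(samples, len(genes)),
        "gene": np.repeat(genes, len(samples)),
        "ct": ct_vals.to_numpy().ravel(),
        "dct": dct.to_numpy().ravel(),
        "ddct": ddct.to_numpy().ravel(),
        "rq": rq.to_numpy().ravel(),
        "censored": censored.to_numpy().ravel(),
    })
    return NormalizedExpression(long, ct.reference_gene, labels)
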