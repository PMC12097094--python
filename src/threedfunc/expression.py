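"""Expression normalization and the expression-change statistic (EC).

EC compares a gene's expression between a cancer group and a normal group
with a Welch two-sample t statistic and reports the lower-tail t CDF at
the observed statistic:

    EC = P( T < (mean_cancer - mean_normal) / sqrt(s_c^2/n_c + s_n^2/n_n) )

with Welch–Satterthwaite degrees of freedom and sample standard
deviations (ddof = 1).  EC near 1 means the gene is up in cancer, near 0
down, 0.5 no change.  Swapping the groups maps EC to 1 - EC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ExpressionMatrix", "fpkm_normalize", "expression_change", "ec_table"]


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values plus per-sample metadata.

    ``values`` is a DataFrame indexed by gene id with sample-id columns;
    ``meta`` is indexed by sample id and carries at least a ``condition``
    column (``cancer`` / ``normal``) and optionally ``aliquot`` /
    ``cell_line`` tags.  ``value_kind`` is one of ``counts``, ``FPKM``,
    ``FPKM-UQ``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    value_kind: str = "counts"

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if "condition" not in self.meta.columns:
            raise ValueError("metadata must carry a 'condition' column")

    def samples(self, condition: str) -> list[str]:
        keep = self.meta.index[self.meta["condition"] == condition]
        return [s for s in self.values.columns if s in set(keep)]


def fpkm_normalize(
    expr: ExpressionMatrix,
    gene_lengths: pd.Series,
    upper_quartile: bool = False,
) -> ExpressionMatrix:
    """Fragments per kilobase of exon per million mapped fragments.

    ``FPKM[g, j] = counts[g, j] * 1e9 / (length_g * libsize_j)`` where
    ``libsize_j`` is the sample's total count.  With ``upper_quartile``
    the per-sample 75th percentile of *nonzero* gene counts replaces the
    total, with an extra 1e3 divisor so the two variants live on a
    comparable scale (the upper quartile is roughly three orders of
    magnitude below a library size; see README).
    """
    if expr.value_kind != "counts":
        raise ValueError(f"expected raw counts, got {expr.value_kind}")
    lengths = gene_lengths.reindex(expr.values.index)
    if lengths.isna().any():
        raise ValueError("every gene needs a length")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    counts = expr.values
    if upper_quartile:
        def _uq(col):
            nz = col[col > 0]
            return np.percentile(nz, 75) if len(nz) else 0.0

        size = counts.apply(_uq, axis=0) * 1e3
        kind = "FPKM-UQ"
    else:
        size = counts.sum(axis=0)
        kind = "FPKM"
    if (size == 0).any():
        bad = list(size.index[size == 0])
        raise ValueError(f"zero library size for samples: {bad}")
    fpkm = counts.mul(1e9).div(lengths, axis=0).div(size, axis=1)
    return ExpressionMatrix(values=fpkm, meta=expr.meta, value_kind=kind)


def _welch_ec(mc, sc, nc, mn, sn, nn):
    """Vectorized Welch lower-tail CDF with degenerate-variance conventions."""
    mc, sc, mn, sn = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(x, dtype=float)) for x in (mc, sc, mn, sn))
    )
    se2 = sc**2 / nc + sn**2 / nn
    ec = np.empty(mc.shape, dtype=float)
    flat = se2 == 0
    # Both variances zero: decided by the sign of the mean difference.
    ec[flat & (mc > mn)] = 1.0
    ec[flat & (mc < mn)] = 0.0
    ec[flat & (mc == mn)] = 0.5
    ok = ~flat
    if ok.any():
        t = (mc[ok] - mn[ok]) / np.sqrt(se2[ok])
        df = se2[ok] ** 2 / (
            (sc[ok] ** 2 / nc) ** 2 / (nc - 1) + (sn[ok] ** 2 / nn) ** 2 / (nn - 1)
        )
        ec[ok] = stats.t.cdf(t, df)
    return ec


def expression_change(
    expr: ExpressionMatrix,
    gene: str,
    cancer_samples,
    normal_samples,
) -> float:
    """EC for one gene between explicit cancer and normal sample sets.

    Requires at least two samples per group.  When both group variances
    are zero the statistic is undefined and EC falls back to 1.0 / 0.0 /
    0.5 by the sign of the mean difference.
    """
    cancer_samples, normal_samples = list(cancer_samples), list(normal_samples)
    if len(cancer_samples) < 2 or len(normal_samples) < 2:
        raise ValueError("need at least 2 samples per group")
    row = expr.values.loc[gene]
    c = row[cancer_samples].to_numpy(dtype=float)
    n = row[normal_samples].to_numpy(dtype=float)
    ec = _welch_ec(
        c.mean(), c.std(ddof=1), len(c), n.mean(), n.std(ddof=1), len(n)
    )
    return float(ec[0])


def ec_table(
    expr: ExpressionMatrix,
    cancer_samples=None,
    normal_samples=None,
) -> pd.Series:
    """EC for every gene at once (vectorized); defaults to the metadata's
    cancer/normal split.  Returns a Series indexed by gene id."""
    cancer_samples = list(cancer_samples) if cancer_samples is not None else expr.samples("cancer")
    normal_samples = list(normal_samples) if normal_samples is not None else expr.samples("normal")
    if len(cancer_samples) < 2 or len(normal_samples) < 2:
        raise ValueError("need at least 2 samples per group")
    C = expr.values[cancer_samples].to_numpy(dtype=float)
    N = expr.values[normal_samples].to_numpy(dtype=float)
    ec = _welch_ec(
        C.mean(axis=1), C.std(axis=1, ddof=1), C.shape[1],
        N.mean(axis=1), N.std(axis=1, ddof=1), N.shape[1],
    )
    return pd.Series(ec, index=expr.values.index, name="EC")


def read_expression_tsv(values_path, meta_path, value_kind: str = "counts") -> ExpressionMatrix:
    """Read a gene × sample TSV (gene ids in the first column) and a
    sample metadata TSV (``sample  condition  [aliquot]``)."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, meta=meta, value_kind=value_kind)
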