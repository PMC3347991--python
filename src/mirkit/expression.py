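"""Comparative-Ct (2^-ddCt) relative quantification across tissues.

Replicates are averaged on the Ct scale before the double delta; the
amplification efficiency is fixed at 2 (no efficiency correction). The
calibrator sample's fold is 1 by construction and replicate spread is
propagated through the exponent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CtMeasurement:
    gene: str
    sample: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError(f"ct must be positive, got {self.ct}")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")


@dataclass(frozen=True)
class RelativeExpression:
    gene: str
    sample: str
    fold: float
    sd_fold: float


def read_ct_table(path: str | Path) -> list[CtMeasurement]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "sample", "replicate", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    return [
        CtMeasurement(
            gene=row.gene, sample=row.sample, replicate=int(row.replicate), ct=float(row.ct)
        )
        for row in df.itertuples()
    ]


def relative_quant(
    ct: Sequence[CtMeasurement],
    reference_gene: str,
    calibrator_sample: str,
) -> list[RelativeExpression]:
    """Fold changes 2^-ddCt of every gene/sample against a reference gene
    and a calibrator sample."""
    df = pd.DataFrame(
        {"gene": m.gene, "sample": m.sample, "ct": m.ct} for m in ct
    )
    samples = sorted(df["sample"].unique())
    genes = sorted(g for g in df["gene"].unique() if g != reference_gene)
    if calibrator_sample not in samples:
        raise ValueError(f"calibrator sample {calibrator_sample!r} missing")
    ref_mean = df[df.gene == reference_gene].groupby("sample")["ct"].mean()
    for s in samples:
        if s not in ref_mean.index:
            raise ValueError(f"reference gene {reference_gene!r} missing in sample {s!r}")
    out: list[RelativeExpression] = []
    gene_mean = df[df.gene != reference_gene].groupby(["gene", "sample"])["ct"].agg(
        ["mean", "std", "count"]
    )
    dct = {
        (g, s): gene_mean.loc[(g, s), "mean"] - ref_mean[s]
        for g, s in gene_mean.index
    }
    for g in genes:
        if (g, calibrator_sample) not in dct:
            raise ValueError(f"gene {g!r} missing in calibrator sample")
        for s in samples:
            if (g, s) not in dct:
                continue
            ddct = dct[(g, s)] - dct[(g, calibrator_sample)]
            fold = float(2.0 ** (-ddct))
            sd_ct = gene_mean.loc[(g, s), "std"]
            sd_ct = 0.0 if (np.isnan(sd_ct)) else float(sd_ct)
            # spread propagated through the exponent: half-width of 2^+/-sd
            sd_fold = fold * float(2.0**sd_ct - 2.0**-sd_ct) / 2.0
            out.append(RelativeExpression(gene=g, sample=s, fold=fold, sd_fold=sd_fold))
    return out


def classify_fold(
    expr: Sequence[RelativeExpression],
    threshold: float = 2.0,
    calibrator_sample: str | None = None,
) -> list[str]:
    """Genes whose fold strictly exceeds ``threshold`` in any non-calibrator
    sample."""
    hits = {
        e.gene
        for e in expr
        if e.sample != calibrator_sample and e.fold > threshold
    }
    return sorted(hits)


def write_expression(expr: Sequence[RelativeExpression], path: str | Path) -> None:
    pd.DataFrame(
        {"gene": e.gene, "sample": e.sample, "fold": e.fold, "sd_fold": e.sd_fold}
        for e in expr
    ).to_csv(path, sep="\t", index=False)
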