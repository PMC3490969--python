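"""5'-vs-3' segment divergence contrast.

Mitochondrial COI divergence between a focal sequence and a panel of
comparators, split at a chosen column into the leading ("barcoding") and
trailing segments, plus the aggregate contrast: segment means, their ratio,
a paired t-test and a Mann-Whitney U test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import Alignment
from .divergence import dxy
from .errors import ArgumentError


@dataclass
class ContrastResult:
    """Aggregate 5'/3' contrast over paired per-comparison divergences.

    ``t_p`` is NaN (with ``zero_variance`` set) when the paired differences
    have no spread; the Mann-Whitney test treats the two lists as unpaired
    samples (two-sided, midrank normal approximation with plain variance —
    no continuity or tie correction, the convention of the classic
    statistics packages this analysis style descends from).
    """

    mean5: float
    mean3: float
    ratio: float
    t_stat: float
    t_p: float
    u_stat: float
    u_p: float
    n: int
    zero_variance: bool = False


def paired_contrast(
    values_5prime: Sequence[float], values_3prime: Sequence[float]
) -> ContrastResult:
    """Segment means, 3'/5' ratio and the two significance tests."""
    v5 = np.asarray(values_5prime, dtype=float)
    v3 = np.asarray(values_3prime, dtype=float)
    if v5.shape != v3.shape:
        raise ArgumentError("segment value lists differ in length")
    if v5.size < 2:
        raise ArgumentError("need at least two paired values")
    mean5, mean3 = float(v5.mean()), float(v3.mean())
    ratio = mean3 / mean5 if mean5 != 0 else math.inf

    diffs = v3 - v5
    zero_var = bool(np.allclose(diffs, diffs[0]) and np.std(diffs) == 0.0)
    if zero_var:
        t_stat, t_p = float("nan"), float("nan")
    else:
        t = stats.ttest_rel(v3, v5)
        t_stat, t_p = float(t.statistic), float(t.pvalue)

    u_stat, u_p = _mann_whitney_plain(v3, v5)
    return ContrastResult(
        mean5=mean5, mean3=mean3, ratio=ratio,
        t_stat=t_stat, t_p=t_p,
        u_stat=u_stat, u_p=u_p,
        n=int(v5.size), zero_variance=zero_var,
    )


def _mann_whitney_plain(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U via the midrank normal approximation with
    plain (uncorrected) variance."""
    n1, n2 = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2.0
    sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    if sd == 0.0:
        return u1, float("nan")
    z = (u1 - mu) / sd
    return u1, float(2.0 * stats.norm.sf(abs(z)))


def segment_divergence_table(
    aln: Alignment,
    focal: str,
    others: Iterable[str],
    split: int,
    model: str = "p",
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-pair Dxy (with SE) for the 5' segment [1, split], the 3' segment
    [split+1, end] and the full region."""
    if not (1 <= split < aln.length):
        raise ArgumentError(
            f"split {split} leaves no 3' segment in a {aln.length}-column region"
        )
    others = list(others)
    seg5 = aln.slice(1, split)
    seg3 = aln.slice(split + 1, aln.length)
    records = []
    for other in others:
        row = {"pair": f"{focal} - {other}"}
        for label, region in (("5prime", seg5), ("3prime", seg3), ("full", aln)):
            res = dxy(region, [focal], [other], model=model,
                      bootstrap_reps=bootstrap_reps, seed=seed)
            row[f"dxy_{label}"] = res.dxy
            row[f"se_{label}"] = res.se
        records.append(row)
    return pd.DataFrame.from_records(records)


def load_printed_coi_table() -> pd.DataFrame:
    """The bundled COI segment divergence table (focal taxon vs comparators).

    Columns: comparison, group (saccharina / laminariales /
    ectocarpales_similar / ectocarpales_other), dxy and SE per segment.
    """
    with resources.files("kelppop.data").joinpath(
        "coi_segment_divergence.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def printed_table_contrasts(
    table: pd.DataFrame | None = None,
) -> dict[str, ContrastResult]:
    """Aggregate contrasts for each comparator group of the printed table."""
    df = table if table is not None else load_printed_coi_table()
    out = {}
    for group, sub in df.groupby("group", sort=False):
        if len(sub) < 2:
            continue
        out[group] = paired_contrast(
            sub["dxy_5prime"].tolist(), sub["dxy_3prime"].tolist()
        )
    return out
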