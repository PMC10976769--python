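"""qRT-PCR relative expression: reference-gene normalization,
2^-ddCt quantification, and compact-letter significance display.

The 2^-ddCt method (Livak & Schmittgen) expresses a gene's abundance
relative to a reference gene (dCt = Ct_target - Ct_reference) and a
calibrator condition (ddCt = dCt_sample - mean dCt_calibrator); the
relative quantity is RQ = 2^-ddCt and log2 fold-change is -ddCt.
Technical replicates are averaged before any differencing; dispersion
(SE) is computed over biological replicates only.  Amplification
efficiency is fixed at 2.0 (no efficiency correction).

Reference genes follow the usual plant qPCR practice for this assay
family: the U6 snRNA for mature miRNAs in both tissues, EF-1a for
mRNA targets in roots and 18S rRNA for mRNA targets in leaves.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import read_tsv, write_tsv

logger = logging.getLogger("mirfam")

#: (molecule class, tissue) -> reference gene id
DEFAULT_REFERENCE_MAP = {
    ("mirna", "root"): "U6",
    ("mirna", "leaf"): "U6",
    ("target", "root"): "EF-1a",
    ("target", "leaf"): "18S",
}

CT_COLUMNS = (
    "tissue", "treatment", "timepoint_h", "gene_id", "gene_class",
    "bio_rep", "tech_rep", "ct",
)

_CONDITION = ["tissue", "treatment", "timepoint_h"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path, required=CT_COLUMNS)
    bad = df[(df["ct"] <= 0) | (df["ct"] >= 45)]
    if len(bad):
        raise ValueError(f"{len(bad)} Ct values outside (0, 45)")
    return df


def normalize(
    cts: pd.DataFrame,
    reference_map: dict[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Per-biological-replicate dCt values.

    Technical replicates are averaged first; dCt = mean Ct(gene) -
    mean Ct(reference) within the same sample (tissue x treatment x
    timepoint x biological replicate).  A sample missing its reference
    gene is an error naming the sample.
    """
    reference_map = reference_map or DEFAULT_REFERENCE_MAP
    ref_genes = set(reference_map.values())
    df = cts.copy()
    tech_mean = (
        df.groupby(_CONDITION + ["gene_id", "gene_class", "bio_rep"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    refs = tech_mean[tech_mean["gene_id"].isin(ref_genes)]
    ref_lookup = {
        (r.tissue, r.treatment, r.timepoint_h, r.bio_rep, r.gene_id): r.ct
        for r in refs.itertuples(index=False)
    }
    rows = []
    targets = tech_mean[~tech_mean["gene_id"].isin(ref_genes)]
    for r in targets.itertuples(index=False):
        key = (r.gene_class, r.tissue)
        if key not in reference_map:
            raise ValueError(f"no reference gene configured for {key}")
        ref_gene = reference_map[key]
        ref_ct = ref_lookup.get((r.tissue, r.treatment, r.timepoint_h, r.bio_rep, ref_gene))
        if ref_ct is None:
            raise ValueError(
                f"reference gene {ref_gene!r} missing for sample "
                f"{r.tissue}/{r.treatment}/{r.timepoint_h}h bio_rep {r.bio_rep}"
            )
        rows.append(
            {
                "tissue": r.tissue,
                "treatment": r.treatment,
                "timepoint_h": r.timepoint_h,
                "gene_id": r.gene_id,
                "bio_rep": r.bio_rep,
                "delta_ct": r.ct - ref_ct,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ExpressionResult:
    """Relative expression of one gene in one condition."""

    gene_id: str
    tissue: str
    treatment: str
    timepoint_h: float
    delta_ct: float
    delta_delta_ct: float
    rq: float  # 2^-ddCt
    log2fc: float  # == -ddCt == log2(rq)
    se: float  # over biological replicates
    n_bio: int
    letter: str = ""


def delta_delta_ct(
    delta_cts: pd.DataFrame,
    calibrator_timepoint: float = 0.0,
    within_treatment: bool = True,
) -> list[ExpressionResult]:
    """2^-ddCt relative quantities against a calibrator condition.

    The calibrator is each gene x tissue x treatment group's own
    ``calibrator_timepoint`` sample (so RQ of the calibrator aggregate
    is exactly 1); set ``within_treatment=False`` to calibrate every
    treatment against the pooled calibrator timepoint of its tissue.
    SE is the standard error of -ddCt over biological replicates.
    """
    results: list[ExpressionResult] = []
    group_cols = ["gene_id", "tissue"] + (["treatment"] if within_treatment else [])
    for key, grp in delta_cts.groupby(group_cols, sort=False):
        cal = grp[grp["timepoint_h"] == calibrator_timepoint]
        if cal.empty:
            raise ValueError(f"no calibrator replicates at {calibrator_timepoint} h for {key}")
        cal_mean = cal["delta_ct"].mean()
        for cond, sub in grp.groupby(_CONDITION, sort=False):
            # mean first, then difference: the calibrator's own ddCt is
            # exactly 0 and its RQ exactly 1
            mean_ddct = float(sub["delta_ct"].mean() - cal_mean)
            ddct = sub["delta_ct"].to_numpy() - cal_mean
            n = len(ddct)
            se = float(ddct.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            results.append(
                ExpressionResult(
                    gene_id=sub["gene_id"].iloc[0],
                    tissue=cond[0],
                    treatment=cond[1],
                    timepoint_h=cond[2],
                    delta_ct=float(sub["delta_ct"].mean()),
                    delta_delta_ct=mean_ddct,
                    rq=float(2.0 ** (-mean_ddct)),
                    log2fc=-mean_ddct,
                    se=se,
                    n_bio=n,
                )
            )
    return results


# ---------------------------------------------------------------------------
# Significance letters
# ---------------------------------------------------------------------------

def significance_letters(
    delta_cts: pd.DataFrame,
    gene_id: str,
    tissue: str,
    treatment: str | None = None,
    alpha: float = 0.05,
    method: str = "tukey",
) -> dict[tuple, str]:
    """Compact letter display over conditions of one gene (and tissue,
    optionally one treatment group).

    All-pairs comparison of per-replicate dCt values — Tukey's HSD by
    default, all-pairs Welch t-tests with ``method="t-test"`` — at
    level ``alpha``; conditions that are not significantly different
    share at least one letter.  Letters are assigned from the highest
    group mean of -dCt (i.e. highest expression gets 'a').  With only
    two groups the t-test is used regardless of ``method``.
    """
    sub = delta_cts[(delta_cts["gene_id"] == gene_id) & (delta_cts["tissue"] == tissue)]
    if treatment is not None:
        sub = sub[sub["treatment"] == treatment]
    group_cols = ["treatment", "timepoint_h"] if treatment is None else ["timepoint_h"]
    groups = {
        (k[0] if isinstance(k, tuple) and len(k) == 1 else k): g["delta_ct"].to_numpy()
        for k, g in sub.groupby(group_cols, sort=True)
    }
    if len(groups) < 2:
        raise ValueError("need at least 2 conditions for letters")
    if any(len(v) < 2 for v in groups.values()):
        logger.warning("a condition has a single replicate; letters withheld")
        return {k: "" for k in groups}
    keys = list(groups)
    not_different = _nonsignificant_pairs(groups, keys, alpha, method)
    # expression ranks by -mean(dCt): lower dCt = higher expression
    means = {k: -float(np.mean(groups[k])) for k in keys}
    return _compact_letters(keys, not_different, means)


def _nonsignificant_pairs(groups, keys, alpha, method) -> set[frozenset]:
    ns: set[frozenset] = set()
    if len(keys) == 2 or method == "t-test":
        for a, b in itertools.combinations(keys, 2):
            _stat, p = stats.ttest_ind(groups[a], groups[b])
            if p >= alpha:
                ns.add(frozenset((a, b)))
        return ns
    if method != "tukey":
        raise ValueError(f"unknown method {method!r}")
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([groups[k] for k in keys])
    labels = np.concatenate([[str(k)] * len(groups[k]) for k in keys])
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    label_of = {str(k): k for k in keys}
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    for row in frame.itertuples(index=False):
        if not row.reject:
            ns.add(frozenset((label_of[str(row.group1)], label_of[str(row.group2)])))
    return ns


def _compact_letters(keys, not_different: set[frozenset], means: dict) -> dict:
    """Letters = maximal cliques of the 'not significantly different'
    graph, ordered by each clique's best mean.  Every non-different
    pair then shares a letter and every different pair never does."""
    adj: dict = {k: set() for k in keys}
    for pair in not_different:
        a, b = tuple(pair)
        adj[a].add(b)
        adj[b].add(a)

    cliques: list[set] = []

    def bron_kerbosch(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(r)
            return
        for v in list(p):
            bron_kerbosch(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    bron_kerbosch(set(), set(keys), set())
    if not cliques:  # fully disconnected graph: every group stands alone
        cliques = [{k} for k in keys]
    cliques.sort(key=lambda c: -max(means[k] for k in c))
    letters = {k: "" for k in keys}
    for idx, clique in enumerate(cliques):
        ch = chr(ord("a") + idx) if idx < 26 else f"z{idx}"
        for k in clique:
            letters[k] += ch
    return {k: "".join(sorted(v)) for k, v in letters.items()}


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def results_table(results: list[ExpressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "tissue": r.tissue,
                "treatment": r.treatment,
                "timepoint_h": r.timepoint_h,
                "delta_ct": r.delta_ct,
                "delta_delta_ct": r.delta_delta_ct,
                "rq": r.rq,
                "log2fc": r.log2fc,
                "se": r.se,
                "n_bio": r.n_bio,
                "letter": r.letter,
            }
            for r in results
        ]
    )


def attach_letters(
    results: list[ExpressionResult],
    delta_cts: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "tukey",
) -> list[ExpressionResult]:
    """Fill the ``letter`` field of each result, comparing timepoints
    within each gene x tissue x treatment group."""
    for (gene, tissue, treatment), _grp in results_table(results).groupby(
        ["gene_id", "tissue", "treatment"], sort=False
    ):
        try:
            letters = significance_letters(
                delta_cts, gene, tissue, treatment, alpha=alpha, method=method
            )
        except ValueError:
            continue
        for r in results:
            if r.gene_id == gene and r.tissue == tissue and r.treatment == treatment:
                r.letter = letters.get(r.timepoint_h, "")
    return results


def write_results(results: list[ExpressionResult], path: str | Path) -> None:
    write_tsv(results_table(results), path)
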