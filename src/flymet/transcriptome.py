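"""Transcriptome summary layer downstream of differential-expression testing.

Covers TPM normalization, PCA / k-means sample QC, dual-control DEG
intersection with directional concordance, gene-set over-representation
(Fisher exact tests with an odds-ratio x -log10(padj) enrichment score),
and 2^-ddCt qRT-PCR summaries.  Differential-expression testing itself is
ingested from precomputed tables; the bundled two-sample log-TPM test is a
stub for end-to-end synthetic runs only and is NOT a negative-binomial DE
method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .multitest import bh_adjust

__all__ = [
    "CountMatrix",
    "DEGTable",
    "HighConfidenceDEGSet",
    "EnrichmentResult",
    "tpm",
    "pca_kmeans",
    "intersect_degs",
    "enrich",
    "enrich_collection",
    "rank_by_score",
    "ddct",
    "stub_de_test",
    "read_gmt",
]


@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-gene exonic lengths (bp)."""

    counts: pd.DataFrame            # genes x samples
    lengths: pd.Series              # bp, indexed by gene
    groups: pd.Series               # sample -> group label

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("every gene needs a length")
        if (self.lengths < 1).any():
            raise ValueError("gene lengths must be >= 1 bp")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")


@dataclass
class DEGTable:
    """Per-gene DE statistics for one contrast (log2FC, p, BH-adjusted p)."""

    data: pd.DataFrame              # index: gene; columns: log2fc, p, padj
    contrast: str

    def __post_init__(self) -> None:
        for c in ("log2fc", "p", "padj"):
            if c not in self.data.columns:
                raise ValueError(f"DEG table missing column {c!r}")
        padj = self.data["padj"]
        if ((padj < 0) | (padj > 1)).any():
            raise ValueError("padj outside [0, 1]")

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        # strict inequality: non-significant is defined as padj >= alpha
        return self.data[self.data["padj"] < alpha]


@dataclass
class HighConfidenceDEGSet:
    """Genes significant against both controls with concordant direction."""

    genes: pd.DataFrame             # index: gene; column: direction in {up, down}
    n_shared: int
    n_concordant: int
    n_discordant: int

    @property
    def concordant_fraction(self) -> float:
        return self.n_concordant / self.n_shared if self.n_shared else float("nan")

    @property
    def up(self) -> pd.Index:
        return self.genes.index[self.genes["direction"] == "up"]

    @property
    def down(self) -> pd.Index:
        return self.genes.index[self.genes["direction"] == "down"]


@dataclass
class EnrichmentResult:
    set_id: str
    a: int                          # overlap
    b: int                          # set only
    c: int                          # DEGs only
    d: int                          # neither
    odds_ratio: float
    p: float
    padj: float = float("nan")
    haldane: bool = False

    @property
    def score(self) -> float:
        """Enrichment score: odds ratio x -log10(adjusted p)."""
        if self.padj <= 0:
            return float("inf")
        return self.odds_ratio * (-np.log10(self.padj))


# ---------------------------------------------------------------------------
# TPM


def tpm(cm: CountMatrix) -> pd.DataFrame:
    """Transcripts per million: RPK = count/kb, TPM = RPK / sum(RPK) * 1e6.

    Each sample's TPM column sums to exactly 1e6.
    """
    rpk = cm.counts.div(cm.lengths / 1000.0, axis=0)
    totals = rpk.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero total RPK in sample(s): {bad}")
    return rpk.div(totals, axis=1) * 1e6


# ---------------------------------------------------------------------------
# PCA / k-means QC


def pca_kmeans(expr: pd.DataFrame, k: int = 2, n_components: int = 2,
               seed: int = 0, n_init: int = 50):
    """Sample-level PCA plus k-means clustering on expression values.

    Genes with zero expression in every sample are removed, each remaining
    gene is z-scored across samples, samples are projected onto principal
    components, and k-means (fixed seed, ``n_init`` restarts, best inertia)
    is run on the PC coordinates.

    Returns (coordinates DataFrame with cluster labels, explained variance
    fractions over all sample-space components, number of genes retained).
    """
    if expr.shape[1] < k:
        raise ValueError("fewer samples than clusters")
    keep = expr.sum(axis=1) > 0
    x = expr.loc[keep]
    sd = x.std(axis=1, ddof=0)
    sd = sd.replace(0, 1.0)        # constant genes carry no signal after centering
    z = x.sub(x.mean(axis=1), axis=0).div(sd, axis=0)
    mat = z.to_numpy().T           # samples x genes
    n_comp_full = min(mat.shape[0], mat.shape[1])
    pca = PCA(n_components=n_comp_full, random_state=seed)
    coords_full = pca.fit_transform(mat)
    coords = coords_full[:, :n_components]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(coords)
    out = pd.DataFrame(coords, index=expr.columns,
                       columns=[f"PC{i+1}" for i in range(coords.shape[1])])
    out["cluster"] = km.labels_
    return out, pca.explained_variance_ratio_, int(keep.sum())


# ---------------------------------------------------------------------------
# DEG intersection / concordance


def intersect_degs(table_a: DEGTable, table_b: DEGTable, alpha: float = 0.05) -> HighConfidenceDEGSet:
    """Dual-control DEG intersection with directional concordance.

    A gene enters the shared set when padj < alpha in both contrasts; it is
    concordant when its log2 fold changes agree in sign.  Only concordant
    genes form the high-confidence set, labelled up/down.
    """
    if len(table_a.data.index.intersection(table_b.data.index)) == 0:
        raise ValueError("DEG tables share no gene ids")
    sig_a = table_a.significant(alpha)
    sig_b = table_b.significant(alpha)
    shared = sig_a.index.intersection(sig_b.index)
    sign_a = np.sign(sig_a.loc[shared, "log2fc"])
    sign_b = np.sign(sig_b.loc[shared, "log2fc"])
    conc = shared[(sign_a * sign_b) > 0]
    direction = pd.Series(np.where(sign_a.loc[conc] > 0, "up", "down"), index=conc, name="direction")
    genes = direction.to_frame()
    return HighConfidenceDEGSet(genes, len(shared), len(conc), len(shared) - len(conc))


# ---------------------------------------------------------------------------
# over-representation


def enrich(deg_set, annotation_set, universe, set_id: str = "") -> EnrichmentResult:
    """Fisher exact over-representation of ``deg_set`` in ``annotation_set``.

    Builds the 2x2 table over ``universe`` (a = overlap, b = set only,
    c = DEG only, d = neither), computes the two-sided Fisher p and the
    sample (cross-product) odds ratio ad/bc, applying a Haldane 0.5
    continuity correction only when a zero cell occurs (flagged).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    deg = set(deg_set) & universe
    ann = set(annotation_set) & universe
    if len(deg) < len(set(deg_set)) or len(ann) < len(set(annotation_set)):
        warnings.warn("genes outside the universe were dropped")
    a = len(deg & ann)
    b = len(ann) - a
    c = len(deg) - a
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = 0 in (a, b, c, d)
    if haldane:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    return EnrichmentResult(set_id, a, b, c, d, (aa * dd) / (bb * cc), float(p), haldane=haldane)


def enrich_collection(deg_set, annotation_sets: dict, universe) -> list[EnrichmentResult]:
    """Run :func:`enrich` over a collection of sets and BH-adjust across it."""
    results = [enrich(deg_set, genes, universe, set_id=name)
               for name, genes in annotation_sets.items()]
    padj = bh_adjust([r.p for r in results])
    for r, q in zip(results, padj):
        r.padj = float(q)
    return results


def rank_by_score(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Descending by enrichment score; ties by smaller padj, then larger overlap."""
    if any(np.isnan(r.padj) for r in results):
        raise ValueError("BH adjustment must be applied before ranking (padj unset)")
    return sorted(results, key=lambda r: (-r.score, r.padj, -r.a))


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"set_id": r.set_id, "overlap": r.a, "set_only": r.b, "deg_only": r.c,
         "neither": r.d, "odds_ratio": r.odds_ratio, "p": r.p, "padj": r.padj,
         "score": r.score, "haldane": r.haldane}
        for r in results
    ])


# ---------------------------------------------------------------------------
# qRT-PCR


def ddct(ct: pd.DataFrame, reference_group: str, target: str, housekeeping: str) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    ``ct`` is long format with columns (sample, group, gene, ct); replicate
    Ct values are averaged per sample x gene first.  dCt = Ct_target -
    Ct_housekeeping per sample; ddCt subtracts the reference-group mean dCt;
    relative expression is 2^-ddCt.
    """
    for c in ("sample", "group", "gene", "ct"):
        if c not in ct.columns:
            raise ValueError(f"Ct table missing column {c!r}")
    mean_ct = ct.groupby(["sample", "group", "gene"])["ct"].mean().reset_index()
    wide = mean_ct.pivot_table(index=["sample", "group"], columns="gene", values="ct")
    for g in (target, housekeeping):
        if g not in wide.columns or wide[g].isna().any():
            raise ValueError(f"missing Ct measurements for {g!r}")
    dct = wide[target] - wide[housekeeping]
    ref = dct.xs(reference_group, level="group")
    if len(ref) == 0:
        raise ValueError(f"no samples in reference group {reference_group!r}")
    ddct_vals = dct - ref.mean()
    out = ddct_vals.reset_index()
    out.columns = ["sample", "group", "ddct"]
    out["rel_expr"] = 2.0 ** (-out["ddct"])
    return out


# ---------------------------------------------------------------------------
# stub DE (synthetic end-to-end runs only)


def stub_de_test(cm: CountMatrix, group_a: str, group_b: str, contrast: str = "stub") -> DEGTable:
    """Two-sample Welch t-test on log2(TPM + 1) with BH adjustment.

    A placeholder to close the loop on synthetic data; it is not a
    negative-binomial DE fit and must not be used for real count data.
    """
    expr = np.log2(tpm(cm) + 1.0)
    cols_a = cm.groups.index[cm.groups == group_a]
    cols_b = cm.groups.index[cm.groups == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 samples per group")
    xa, xb = expr[cols_a].to_numpy(), expr[cols_b].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)
    df = pd.DataFrame({"log2fc": log2fc, "p": p, "padj": bh_adjust(p)}, index=expr.index)
    return DEGTable(df, contrast)


# ---------------------------------------------------------------------------
# I/O helpers


def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def read_deg_table(path, contrast: str = "") -> DEGTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.rename(columns={"log2FC": "log2fc", "log2FoldChange": "log2fc",
                            "pvalue": "p", "P": "p"})
    return DEGTable(df, contrast or str(path))


def read_ortholog_map(path, min_confidence: float = 0.0) -> dict[str, set]:
    """DIOPT-style ortholog table (gene, ortholog, confidence) -> mapping.

    Rows below ``min_confidence`` are dropped; the high-confidence cutoff is
    a configuration choice.
    """
    df = pd.read_csv(path, sep="\t")
    gene_col, orth_col, conf_col = df.columns[:3]
    df = df[df[conf_col] >= min_confidence]
    out: dict[str, set] = {}
    for g, o in zip(df[gene_col], df[orth_col]):
        out.setdefault(str(g), set()).add(str(o))
    return out


def map_orthologs(genes, mapping: dict[str, set]) -> set:
    """Project a gene collection through an ortholog map (union of targets)."""
    out: set = set()
    for g in genes:
        out |= mapping.get(str(g), set())
    return out


def read_counts(counts_path, lengths_path, groups: dict | pd.Series) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(counts, lengths, pd.Series(groups))
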