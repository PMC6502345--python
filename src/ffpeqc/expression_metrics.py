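"""Expression-level QC computations for degraded-RNA RNA-Seq.

Operates on a genes x samples expression matrix (raw counts plus TPM) and on
per-sample diagnostic profiles:

* noise filtering (drop genes below TPM >= 1 / count >= 5 in every sample),
* genes-detected counting (strictly more than a minimum read count),
* replicate concordance (Pearson over log2(TPM+1) of filter-passing genes),
* signature-set concordance against a reference expression profile, with
  hierarchical clustering of samples into quality classes (the best class
  tracks the reference; the worst has too few signature reads to assess),
* gene-body coverage bias (3'/5' enrichment over 100 positional bins,
  stratified by mRNA content),
* GC-content profile anomaly flags (excess read mass at extreme GC),
* a PCA view of samples for outlier spotting.

Defaults that the underlying study protocols leave open are pinned here and
stated in docstrings: log2(TPM+1) as the correlation/clustering scale,
average linkage on 1 - Pearson distance, three quality classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

__all__ = [
    "ExpressionMatrix",
    "GeneBodyProfile",
    "GCProfile",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_list",
    "read_profile",
    "ConcordanceResult",
    "GeneBodyBiasReport",
    "GCFlags",
    "filter_low_expression",
    "low_expression_mask",
    "genes_detected",
    "replicate_correlation",
    "signature_concordance",
    "gene_body_bias",
    "gc_anomaly_flags",
    "replicate_pca",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression: raw counts and TPM side by side."""

    gene_ids: List[str]
    sample_ids: List[str]
    raw_counts: np.ndarray
    tpm: np.ndarray

    def __post_init__(self):
        self.raw_counts = np.asarray(self.raw_counts)
        self.tpm = np.asarray(self.tpm, dtype=float)
        g, s = len(self.gene_ids), len(self.sample_ids)
        if self.raw_counts.shape != (g, s) or self.tpm.shape != (g, s):
            raise ValueError("matrix shapes must be (n_genes, n_samples)")
        if np.any(self.raw_counts < 0) or np.any(self.tpm < 0):
            raise ValueError("counts and TPM must be non-negative")

    @classmethod
    def from_counts(
        cls,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        raw_counts: np.ndarray,
        gene_lengths: np.ndarray,
    ) -> "ExpressionMatrix":
        """Build TPM from counts and effective gene lengths (nt).

        TPM_gs = 1e6 * (count_gs / length_g) / sum_g'(count_g's / length_g').
        All-zero samples get all-zero TPM.
        """
        counts = np.asarray(raw_counts, dtype=float)
        lengths = np.asarray(gene_lengths, dtype=float)
        if np.any(lengths <= 0):
            raise ValueError("gene lengths must be positive")
        rate = counts / lengths[:, None]
        denom = rate.sum(axis=0)
        tpm = np.divide(
            rate * 1e6, denom[None, :], out=np.zeros_like(rate), where=denom > 0
        )
        return cls(list(gene_ids), list(sample_ids), np.asarray(raw_counts), tpm)

    def column(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        return ExpressionMatrix(
            [g for g, k in zip(self.gene_ids, keep) if k],
            list(self.sample_ids),
            self.raw_counts[keep],
            self.tpm[keep],
        )


@dataclass
class GeneBodyProfile:
    """Read coverage over 100 normalized transcript-position bins (5'->3')."""

    sample_id: str
    bins: np.ndarray
    mrna_pct: float

    def __post_init__(self):
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (100,):
            raise ValueError("gene-body profile must have exactly 100 bins")
        if np.any(self.bins < 0):
            raise ValueError("coverage must be non-negative")


@dataclass
class GCProfile:
    """Read counts over 100 GC-percent bins (bin i covers [i, i+1) % GC)."""

    sample_id: str
    gc_bins: np.ndarray

    def __post_init__(self):
        self.gc_bins = np.asarray(self.gc_bins, dtype=float)
        if self.gc_bins.shape != (100,):
            raise ValueError("GC profile must have exactly 100 bins")
        if np.any(self.gc_bins < 0):
            raise ValueError("read counts must be non-negative")


def _read_genes_by_samples(path) -> pd.DataFrame:
    p = Path(path)
    if p.suffix == ".mtx":
        from scipy.io import mmread

        genes = Path(str(p) + ".genes").read_text().split()
        samples = Path(str(p) + ".samples").read_text().split()
        raw = mmread(p)
        mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw)
        return pd.DataFrame(mat, index=genes, columns=samples)
    return pd.read_csv(p, sep=None, engine="python", index_col=0)


def read_expression_matrix(
    counts_path, tpm_path=None, gene_lengths_path=None
) -> ExpressionMatrix:
    """Read counts (and TPM) from delimited text or matrix-market files.

    Delimited files are genes x samples with a gene-id index column and a
    sample-id header; a ``.mtx`` file expects sibling ``<file>.genes`` /
    ``<file>.samples`` id lists. Provide either a TPM file on the same
    gene/sample grid or a two-column (gene, length-nt) file from which TPM
    is computed.
    """
    counts = _read_genes_by_samples(counts_path)
    if tpm_path is not None:
        tpm = _read_genes_by_samples(tpm_path)
        tpm = tpm.loc[counts.index, counts.columns]
        return ExpressionMatrix(
            list(counts.index), list(counts.columns),
            counts.to_numpy(), tpm.to_numpy(dtype=float),
        )
    if gene_lengths_path is not None:
        lengths = pd.read_csv(
            gene_lengths_path, sep=None, engine="python", index_col=0
        ).iloc[:, 0]
        return ExpressionMatrix.from_counts(
            list(counts.index), list(counts.columns),
            counts.to_numpy(), lengths.loc[counts.index].to_numpy(dtype=float),
        )
    raise ValueError("provide tpm_path or gene_lengths_path")


def write_expression_matrix(m: ExpressionMatrix, counts_path, tpm_path) -> None:
    """Write counts and TPM as tab-delimited genes x samples tables."""
    pd.DataFrame(m.raw_counts, index=m.gene_ids, columns=m.sample_ids).to_csv(
        counts_path, sep="\t", index_label="gene_id"
    )
    pd.DataFrame(m.tpm, index=m.gene_ids, columns=m.sample_ids).to_csv(
        tpm_path, sep="\t", index_label="gene_id"
    )


def read_gene_list(path) -> List[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        s = line.split("#", 1)[0].strip()
        if s:
            out.append(s)
    return out


def read_profile(path, sample_id: Optional[str] = None):
    """Read a 100-row profile file (bin index, value) as a plain array.

    ``# mrna_pct=<x>`` comment lines are honoured; returns ``(sample_id,
    values, mrna_pct-or-None)``. Feed the result to :class:`GeneBodyProfile`
    or :class:`GCProfile` as appropriate.
    """
    mrna = None
    values = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        s = line.strip()
        if s.startswith("#"):
            if "mrna_pct=" in s:
                mrna = float(s.split("mrna_pct=")[1])
            continue
        if not s:
            continue
        parts = s.replace(",", "\t").split()
        try:
            values.append(float(parts[-1]))
        except ValueError:
            continue  # header
    sid = sample_id or Path(path).stem
    return sid, np.asarray(values, dtype=float), mrna


def low_expression_mask(
    m: ExpressionMatrix, *, tpm_min: float = 1.0, count_min: int = 5
) -> np.ndarray:
    """Boolean (genes x samples) mask of entries clearing the noise floor.

    An entry passes when TPM >= tpm_min and raw count >= count_min (the
    thresholds are "below is noise", so boundary values pass).
    """
    return (m.tpm >= tpm_min) & (m.raw_counts >= count_min)


def filter_low_expression(
    m: ExpressionMatrix, *, tpm_min: float = 1.0, count_min: int = 5
) -> ExpressionMatrix:
    """Drop genes that fail the noise threshold in every sample.

    A gene survives if at least one sample has TPM >= tpm_min and raw count
    >= count_min. Idempotent; TPM values are carried over unrenormalized so
    repeated application changes nothing. Per-sample masking is available
    separately via :func:`low_expression_mask`.
    """
    keep = low_expression_mask(m, tpm_min=tpm_min, count_min=count_min).any(axis=1)
    return m.subset_genes(keep)


def genes_detected(counts: np.ndarray, min_reads: int = 5) -> int:
    """Number of genes with strictly more than ``min_reads`` mapped reads."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return int((counts > min_reads).sum())


def replicate_correlation(
    m: ExpressionMatrix,
    pairs: Sequence[Tuple[str, str]],
    *,
    transform: str = "log2",
    tpm_min: float = 1.0,
    count_min: int = 5,
) -> Dict[Tuple[str, str], float]:
    """Pearson correlation of expression between members of each sample pair.

    For each pair, genes passing the noise threshold in *either* member are
    used; values are log2(TPM+1) by default (``transform="raw"`` for plain
    TPM). The transform choice is part of the returned contract, not an
    internal detail — concordance bands quoted for replicates refer to this
    scale.
    """
    if transform not in ("log2", "raw"):
        raise ValueError("transform must be 'log2' or 'raw'")
    mask = low_expression_mask(m, tpm_min=tpm_min, count_min=count_min)
    out: Dict[Tuple[str, str], float] = {}
    for a, b in pairs:
        ia, ib = m.column(a), m.column(b)
        genes = mask[:, ia] | mask[:, ib]
        if genes.sum() < 3:
            out[(a, b)] = float("nan")
            continue
        x = m.tpm[genes, ia]
        y = m.tpm[genes, ib]
        if transform == "log2":
            x = np.log2(x + 1.0)
            y = np.log2(y + 1.0)
        out[(a, b)] = float(np.corrcoef(x, y)[0, 1])
    return out


@dataclass
class ConcordanceResult:
    """Per-sample concordance with a reference profile plus quality classes.

    ``concordance`` is NaN for excluded samples (too few signature genes with
    enough reads — the hallmark of the worst class, which they are assigned
    to directly). ``labels`` partition all samples into classes "B", "C", ...
    ordered by decreasing median concordance; ``linkage`` is the scipy
    linkage matrix over the clustered (non-excluded) samples.
    """

    sample_ids: List[str]
    concordance: np.ndarray
    labels: List[str]
    excluded: Dict[str, str]
    linkage: Optional[np.ndarray]
    description: str = ""

    def label_of(self, sample_id: str) -> str:
        return self.labels[self.sample_ids.index(sample_id)]


def signature_concordance(
    m: ExpressionMatrix,
    signature: Sequence[str],
    reference: np.ndarray,
    *,
    min_reads: int = 5,
    min_genes: int = 3,
    n_classes: int = 3,
) -> ConcordanceResult:
    """Concordance of each sample's signature-gene profile with a reference.

    The matrix is subset to signature genes; per sample, only genes with at
    least ``min_reads`` raw counts are usable, and samples with fewer than
    ``min_genes`` usable genes are excluded (reported with a reason) and
    assigned the worst class outright. Concordance is Pearson between
    log2(TPM+1) of the sample's usable signature genes and the matching
    entries of ``reference`` (a log2(TPM+1) expression vector aligned to
    ``signature``).

    Remaining samples are hierarchically clustered (average linkage on
    1 - Pearson over their full signature vectors) and cut into quality
    classes labelled "B", "C", ... by decreasing median concordance; when
    exclusions exist the last label is reserved for them.
    """
    sig_index = {g: i for i, g in enumerate(m.gene_ids)}
    present = [g for g in signature if g in sig_index]
    if len(present) < min_genes:
        raise ValueError("signature not represented")
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (len(signature),):
        raise ValueError("reference must align with the signature gene list")
    ref_present = np.array(
        [ref[list(signature).index(g)] for g in present], dtype=float
    )
    rows = np.array([sig_index[g] for g in present])
    counts = m.raw_counts[rows]
    logtpm = np.log2(m.tpm[rows] + 1.0)

    n = len(m.sample_ids)
    conc = np.full(n, np.nan)
    excluded: Dict[str, str] = {}
    for j, sid in enumerate(m.sample_ids):
        usable = counts[:, j] >= min_reads
        if usable.sum() < min_genes:
            excluded[sid] = (
                f"only {int(usable.sum())} signature genes with >= {min_reads} reads"
            )
            continue
        x = logtpm[usable, j]
        r = ref_present[usable]
        if np.ptp(x) == 0 or np.ptp(r) == 0:
            conc[j] = 0.0
        else:
            conc[j] = float(np.corrcoef(x, r)[0, 1])

    included = [j for j, s in enumerate(m.sample_ids) if s not in excluded]
    labels = [""] * n
    linkage_matrix = None
    alphabet = [chr(ord("B") + i) for i in range(max(n_classes, 2))]
    worst = alphabet[n_classes - 1]
    for sid in excluded:
        labels[m.sample_ids.index(sid)] = worst

    if included:
        k_avail = n_classes - (1 if excluded else 0)
        k = max(1, min(k_avail, len(included)))
        x = logtpm[:, included].T  # samples x genes
        if len(included) == 1:
            cluster_ids = np.array([1])
        else:
            xc = x - x.mean(axis=1, keepdims=True)
            norm = np.linalg.norm(xc, axis=1)
            norm[norm == 0] = 1.0
            corr = np.clip((xc / norm[:, None]) @ (xc / norm[:, None]).T, -1, 1)
            dist = 1.0 - corr
            np.fill_diagonal(dist, 0.0)
            dist = (dist + dist.T) / 2  # enforce exact symmetry
            linkage_matrix = average(squareform(dist, checks=False))
            cluster_ids = fcluster(linkage_matrix, t=k, criterion="maxclust")
        # order clusters by decreasing median concordance
        meds = {}
        for cid in np.unique(cluster_ids):
            members = [included[i] for i in np.where(cluster_ids == cid)[0]]
            meds[cid] = float(np.nanmedian(conc[members]))
        order = sorted(meds, key=lambda c: -meds[c])
        for rank, cid in enumerate(order):
            for i in np.where(cluster_ids == cid)[0]:
                labels[included[i]] = alphabet[rank]

    desc = (
        f"average linkage on 1-Pearson, {n_classes} classes, "
        f"{len(included)} clustered / {len(excluded)} excluded"
    )
    return ConcordanceResult(
        sample_ids=list(m.sample_ids),
        concordance=conc,
        labels=labels,
        excluded=excluded,
        linkage=linkage_matrix,
        description=desc,
    )


@dataclass
class GeneBodyBiasReport:
    """Per-sample 3'/5' coverage bias plus mRNA-stratified mean curves.

    ``per_sample`` columns: bias5, bias3 (mean coverage of the first/last 20
    bins over the middle 20, after unit-mean normalization), flags, mrna_pct.
    ``strata_curves`` maps ``"high_mrna"``/``"low_mrna"`` to mean normalized
    100-bin curves (NaN-free only when the stratum is non-empty).
    """

    per_sample: pd.DataFrame
    strata_curves: Dict[str, np.ndarray]
    excluded: Dict[str, str]
    flag_ratio: float
    mrna_split_pct: float


def gene_body_bias(
    profiles: Sequence[GeneBodyProfile],
    *,
    flag_ratio: float = 1.5,
    mrna_split_pct: float = 10.0,
) -> GeneBodyBiasReport:
    """Quantify 5'/3' coverage bias and stratify curves by mRNA content.

    Each profile is normalized to unit mean; bias5 = mean(bins 1-20) /
    mean(bins 41-60), bias3 = mean(bins 81-100) / mean(bins 41-60). A bias
    flag fires above ``flag_ratio``. The windows and the 1.5 default are
    package conventions (coverage-bias figures are usually shown without a
    numeric score). Zero-coverage profiles are excluded with a reason.
    """
    rows = []
    excluded: Dict[str, str] = {}
    high, low = [], []
    for p in profiles:
        total = p.bins.sum()
        if total <= 0:
            excluded[p.sample_id] = "zero coverage"
            continue
        norm = p.bins / p.bins.mean()
        mid = norm[40:60].mean()
        if mid == 0:
            excluded[p.sample_id] = "zero mid-transcript coverage"
            continue
        bias5 = float(norm[0:20].mean() / mid)
        bias3 = float(norm[80:100].mean() / mid)
        rows.append(
            {
                "sample_id": p.sample_id,
                "bias5": bias5,
                "bias3": bias3,
                "flag_5prime": bias5 > flag_ratio,
                "flag_3prime": bias3 > flag_ratio,
                "mrna_pct": p.mrna_pct,
            }
        )
        (high if p.mrna_pct > mrna_split_pct else low).append(norm)
    curves = {
        "high_mrna": np.mean(high, axis=0) if high else np.full(100, np.nan),
        "low_mrna": np.mean(low, axis=0) if low else np.full(100, np.nan),
    }
    return GeneBodyBiasReport(
        per_sample=pd.DataFrame(
            rows,
            columns=[
                "sample_id", "bias5", "bias3", "flag_5prime", "flag_3prime", "mrna_pct",
            ],
        ),
        strata_curves=curves,
        excluded=excluded,
        flag_ratio=flag_ratio,
        mrna_split_pct=mrna_split_pct,
    )


@dataclass
class GCFlags:
    """Fractions of read mass at extreme GC and the resulting flags.

    Human RNA-Seq read GC normally concentrates in the 40-60% band; excess
    mass at <= low_cut or >= high_cut percent GC marks artifact peaks.
    """

    sample_id: str
    frac_low_gc: float
    frac_high_gc: float
    frac_normal_band: float
    low_gc_flag: bool
    high_gc_flag: bool
    bulk_in_normal_band: bool


def gc_anomaly_flags(
    profile: GCProfile,
    *,
    low_cut: float = 10.0,
    high_cut: float = 80.0,
    frac_threshold: float = 0.05,
) -> GCFlags:
    """Flag abnormal low/high-GC read mass in a 100-bin GC profile.

    Bin i holds reads with GC in [i, i+1)%, so "GC <= 10%" covers bins 0-9
    and "GC >= 80%" bins 80-99. Flags fire when either tail fraction exceeds
    ``frac_threshold`` of all reads. An all-zero profile reports zero
    fractions and no flags.
    """
    total = profile.gc_bins.sum()
    if total <= 0:
        return GCFlags(profile.sample_id, 0.0, 0.0, 0.0, False, False, False)
    centers = np.arange(100) + 0.5
    frac_low = float(profile.gc_bins[centers <= low_cut].sum() / total)
    frac_high = float(profile.gc_bins[centers >= high_cut].sum() / total)
    frac_mid = float(profile.gc_bins[(centers >= 40) & (centers <= 60)].sum() / total)
    return GCFlags(
        sample_id=profile.sample_id,
        frac_low_gc=frac_low,
        frac_high_gc=frac_high,
        frac_normal_band=frac_mid,
        low_gc_flag=frac_low > frac_threshold,
        high_gc_flag=frac_high > frac_threshold,
        bulk_in_normal_band=frac_mid >= 0.5,
    )


def replicate_pca(
    m: ExpressionMatrix,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
    *,
    n_components: int = 2,
) -> pd.DataFrame:
    """Project samples onto the first principal components of log2(TPM+1).

    Operates on the noise-filtered matrix; components' signs follow the
    convention that each component's largest-magnitude gene loading is
    positive, making the projection deterministic. Returns a DataFrame
    indexed by sample id with PC1..PCk columns (and, when ``pairs`` is
    given, a ``pair`` column naming each sample's replicate pair or "").
    """
    if len(m.sample_ids) < 3:
        raise ValueError("need at least 3 samples for PCA")
    filt = filter_low_expression(m)
    x = np.log2(filt.tpm + 1.0).T  # samples x genes
    k = min(n_components, len(m.sample_ids) - 1, x.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    proj = pca.fit_transform(x)
    for c in range(k):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[c] = -load
            proj[:, c] = -proj[:, c]
    df = pd.DataFrame(
        proj, index=list(m.sample_ids), columns=[f"PC{i+1}" for i in range(k)]
    )
    df.index.name = "sample_id"
    if pairs is not None:
        pair_of = {}
        for a, b in pairs:
            pair_of[a] = f"{a}|{b}"
            pair_of[b] = f"{a}|{b}"
        df["pair"] = [pair_of.get(s, "") for s in m.sample_ids]
    return df
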