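"""Expression quantification (FPKM, tag-based TPM) and threshold-based
differential-expression calling between two libraries.

FPKM normalises fragment counts by gene length (kb) and library size
(millions); TPM here is the digital-gene-expression sense: tag count per
million clean tags, where a tag is the 21-mer anchored at a CATG (NlaIII)
site plus the 17 downstream bases.  Differentially expressed transcripts
(DETs) are called per gene by a two-sided hypergeometric test combined with
p <= alpha and |log2 fold change| >= threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

TAG_ANCHOR = "CATG"
TAG_LEN = 21  # CATG + 17 downstream bases


@dataclass
class CountTable:
    genes: list[str]
    libraries: list[str]
    counts: np.ndarray                 # genes x libraries, non-negative ints
    gene_lengths: np.ndarray           # bp
    library_sizes: np.ndarray          # total mapped fragments / clean tags

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=np.int64)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.counts.shape != (len(self.genes), len(self.libraries)):
            raise ValueError("count matrix shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        colsums = self.counts.sum(axis=0)
        if (self.library_sizes < colsums).any():
            raise ValueError("library_sizes must be >= column sums")

    def column(self, library: str) -> np.ndarray:
        return self.counts[:, self.libraries.index(library)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.libraries)

    @classmethod
    def from_tsv(cls, counts_path, lengths_path, library_sizes=None) -> "CountTable":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        lens = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
        lens = lens.reindex(df.index)
        if lens.isna().any():
            raise ValueError("missing gene lengths for some genes")
        sizes = (
            np.asarray([library_sizes[c] for c in df.columns])
            if library_sizes
            else df.sum(axis=0).to_numpy()
        )
        return cls(
            genes=list(df.index),
            libraries=list(df.columns),
            counts=df.to_numpy(),
            gene_lengths=lens.to_numpy(),
            library_sizes=sizes,
        )


def fpkm(count: float, gene_length_bp: float, library_size: float) -> float:
    """Fragments per kilobase per million mapped fragments."""
    if gene_length_bp <= 0 or library_size <= 0:
        raise ValueError("gene length and library size must be positive")
    return count * 1e9 / (gene_length_bp * library_size)


def fpkm_table(table: CountTable) -> pd.DataFrame:
    mat = (
        table.counts
        * 1e9
        / (table.gene_lengths[:, None] * table.library_sizes[None, :])
    )
    return pd.DataFrame(mat, index=table.genes, columns=table.libraries)


def tpm(tag_count: float, total_clean_tags: float) -> float:
    """Tags per million clean tags."""
    if total_clean_tags <= 0:
        raise ValueError("total clean tags must be positive")
    return tag_count * 1e6 / total_clean_tags


def tpm_table(table: CountTable) -> pd.DataFrame:
    mat = table.counts * 1e6 / table.library_sizes[None, :]
    return pd.DataFrame(mat, index=table.genes, columns=table.libraries)


def extract_tags(transcript: str, mode: str = "all") -> list[str]:
    """21-bp DGE tags: each CATG with >= 17 downstream bases.

    ``three_prime_most`` keeps only the occurrence closest to the 3' end;
    tags are returned 5'->3'.
    """
    if mode not in ("all", "three_prime_most"):
        raise ValueError(f"unknown tag mode {mode!r}")
    transcript = transcript.upper().replace("U", "T")
    tags = []
    start = 0
    while True:
        i = transcript.find(TAG_ANCHOR, start)
        if i < 0:
            break
        if i + TAG_LEN <= len(transcript):
            tags.append(transcript[i : i + TAG_LEN])
        start = i + 1
    if mode == "three_prime_most" and tags:
        return [tags[-1]]
    return tags


def map_tags_to_genes(tags_by_gene: dict[str, list[str]]):
    """Assign tags uniquely; a tag matching more than one gene is ambiguous."""
    owners: dict[str, set] = {}
    for gene, tags in tags_by_gene.items():
        for t in tags:
            owners.setdefault(t, set()).add(gene)
    unique = {t: next(iter(g)) for t, g in owners.items() if len(g) == 1}
    ambiguous = sorted(t for t, g in owners.items() if len(g) > 1)
    return unique, ambiguous


# ---------------------------------------------------------------------------
# hypergeometric two-sided test


def _log_pmf_terms(ks: np.ndarray, M: int, K: int, N: int) -> np.ndarray:
    return (
        gammaln(K + 1)
        - gammaln(ks + 1)
        - gammaln(K - ks + 1)
        + gammaln(M - K + 1)
        - gammaln(N - ks + 1)
        - gammaln(M - K - N + ks + 1)
        - (gammaln(M + 1) - gammaln(N + 1) - gammaln(M - N + 1))
    )


def hypergeom_two_sided(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided hypergeometric p-value by tail doubling.

    Conditions on the margins: population n1+n2, successes x1+x2, sample n1;
    p = min(1, 2 * min(P[X <= x1], P[X >= x1])).  The smaller tail is summed
    directly in log space for numerical stability.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n for both libraries")
    if n1 + n2 > 10**8:
        raise ValueError("margins too large")
    M, K, N = n1 + n2, x1 + x2, n1
    kmin, kmax = max(0, K - n2), min(K, n1)
    mean = N * K / M

    def tail(lo: int, hi: int) -> float:
        ks = np.arange(lo, hi + 1, dtype=np.float64)
        return float(math.fsum(np.exp(_log_pmf_terms(ks, M, K, N))))

    if x1 <= mean:
        p_le = tail(kmin, x1)
        pmf_x = tail(x1, x1)
        p_ge = 1.0 - p_le + pmf_x
    else:
        p_ge = tail(x1, kmax)
        pmf_x = tail(x1, x1)
        p_le = 1.0 - p_ge + pmf_x
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------------------
# DET calling


@dataclass
class DetParams:
    alpha: float = 0.05
    fc_threshold: float = 1.0
    pseudocount: float = 1.0
    adjust: str = "none"  # 'none' | 'BH'

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if self.fc_threshold < 0:
            raise ValueError("fc_threshold must be >= 0")
        if self.adjust not in ("none", "BH"):
            raise ValueError("adjust must be 'none' or 'BH'")


@dataclass
class DetResult:
    gene: str
    log2fc: float
    p_value: float
    direction: str            # 'up' | 'down' (in the first library)
    significant: bool
    adjusted_p: float | None = None


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_dets(
    table: CountTable, lib_a: str, lib_b: str, params: DetParams | None = None
) -> list[DetResult]:
    """Per-gene DET calls between two libraries, sorted by p-value.

    log2fc uses a pseudocount on the rates (never on the test);
    significance requires p (or BH-adjusted p) <= alpha AND
    |log2fc| >= fc_threshold.
    """
    params = params or DetParams()
    ca = table.column(lib_a).astype(float)
    cb = table.column(lib_b).astype(float)
    sa = float(table.library_sizes[table.libraries.index(lib_a)])
    sb = float(table.library_sizes[table.libraries.index(lib_b)])
    pc = params.pseudocount
    lfc = np.log2(((ca + pc) / sa) / ((cb + pc) / sb))
    pvals = np.array(
        [
            hypergeom_two_sided(int(a), int(sa), int(b), int(sb))
            for a, b in zip(ca, cb)
        ]
    )
    adj = benjamini_hochberg(pvals) if params.adjust == "BH" else None
    crit = adj if adj is not None else pvals
    results = []
    for i, gene in enumerate(table.genes):
        significant = bool(
            crit[i] <= params.alpha and abs(lfc[i]) >= params.fc_threshold
        )
        results.append(
            DetResult(
                gene=gene,
                log2fc=float(lfc[i]),
                p_value=float(pvals[i]),
                direction="up" if lfc[i] > 0 else "down",
                significant=significant,
                adjusted_p=None if adj is None else float(adj[i]),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.gene))
    return results
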