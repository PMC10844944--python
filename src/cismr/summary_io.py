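"""Reading, validation and allele harmonisation of GWAS summary statistics.

Summary statistics are held as :class:`pandas.DataFrame` objects with the
canonical columns

    chrom, pos, rsid, ea, oa, eaf, beta, se, pvalue, n

where ``ea`` is the effect allele, ``oa`` the other allele, ``eaf`` the
effect-allele frequency, ``beta`` the per-allele effect (SD units for
quantitative protein traits, log-odds for case-control outcomes) and ``se``
its standard error.  Positions are 1-based on a single genome build; variants
are matched across datasets on ``(chrom, pos)``, with rsids used only for
reporting.  Only biallelic SNPs (single upper-case A/C/G/T alleles) are
accepted; indels and multi-allelic records are rejected at read time.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order for summary-statistic frames
COLUMNS = ["chrom", "pos", "rsid", "ea", "oa", "eaf", "beta", "se", "pvalue", "n"]

_NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class VariantKey:
    """Identity of one biallelic SNP: coordinates plus allele pair."""

    chrom: str
    pos: int
    rsid: str
    ea: str
    oa: str

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}"


def variant_key(chrom, pos) -> str:
    """String key used to index variants across tables and LD matrices."""
    return f"{chrom}:{int(pos)}"


def is_strand_ambiguous(ea: str, oa: str) -> bool:
    """True iff the allele pair is palindromic ({A,T} or {C,G}).

    Such SNPs cannot be strand-resolved from alleles alone and are dropped
    during harmonisation when their minor allele frequency exceeds the
    palindrome limit (0.40 by default).
    """
    pair = {ea, oa}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw summary frame into valid records and rejects.

    Returns ``(clean, rejects)`` where ``rejects`` carries a ``reason`` column
    and the original (0-based) ``row`` index.  Validity follows the record
    invariants: single-nucleotide distinct alleles, 0 < eaf < 1, se > 0,
    p in (0, 1], pos >= 1.  A p-value drifting more than 10% (relative, on the
    implied |z|) from the normal two-sided p of beta/se is only warned about.
    """
    df = df.copy()
    df["row"] = np.arange(len(df))
    reasons = pd.Series("", index=df.index, dtype=object)

    ea = df["ea"].astype(str).str.upper()
    oa = df["oa"].astype(str).str.upper()
    df["ea"], df["oa"] = ea, oa
    bad_allele = (
        ~ea.isin(_NUCLEOTIDES) | ~oa.isin(_NUCLEOTIDES) | (ea == oa)
    )
    reasons[bad_allele & (reasons == "")] = "invalid_alleles"

    num = df[["pos", "eaf", "beta", "se", "pvalue", "n"]].apply(
        pd.to_numeric, errors="coerce"
    )
    df[num.columns] = num
    bad_num = num.isna().any(axis=1)
    reasons[bad_num & (reasons == "")] = "non_numeric"

    with np.errstate(invalid="ignore"):
        bad_range = (
            (num["eaf"] <= 0)
            | (num["eaf"] >= 1)
            | (num["se"] <= 0)
            | (num["pvalue"] <= 0)
            | (num["pvalue"] > 1)
            | (num["pos"] < 1)
        )
    reasons[bad_range.fillna(False) & (reasons == "")] = "invalid_range"

    ok = reasons == ""
    clean = df.loc[ok].copy()
    clean["pos"] = clean["pos"].astype(int)
    clean["n"] = clean["n"].astype(float)
    rejects = df.loc[~ok].copy()
    rejects["reason"] = reasons[~ok]

    if len(clean):
        z = np.abs(clean["beta"] / clean["se"])
        z_imp = np.abs(stats.norm.isf(np.clip(clean["pvalue"], 1e-300, 1) / 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(z - z_imp) / np.where(z_imp > 0, z_imp, np.inf)
        n_off = int((rel > 0.10).sum())
        if n_off:
            logger.warning(
                "%d records have p-values >10%% off the normal beta/se p", n_off
            )
    return clean.reset_index(drop=True), rejects.reset_index(drop=True)


def read_summary(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read a tab/comma-delimited summary-statistic table.

    ``dialect`` maps canonical column names to the file's column names, e.g.
    ``{"chrom": "CHR", "pos": "BP", ...}``; canonical names are assumed where
    absent.  Malformed rows are dropped and logged with their line numbers.
    Rejected rows are available on the returned frame as ``.attrs["rejects"]``.
    """
    with _open_text(path) as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") >= first.count(",") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    dialect = dialect or {}
    rename = {src: canon for canon, src in dialect.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    raw = raw[COLUMNS]
    clean, rejects = validate_records(raw)
    for _, r in rejects.iterrows():
        logger.warning(
            "%s: line %d rejected (%s)", path, int(r["row"]) + 2, r["reason"]
        )
    clean = clean.drop(columns="row")
    clean.attrs["rejects"] = rejects
    return clean


def write_summary(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a summary-statistic frame in the canonical dialect."""
    cols = [c for c in COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in COLUMNS
    ]
    df[cols].to_csv(path, sep=sep, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# harmonisation


def harmonise(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_maf_limit: float = 0.40,
) -> pd.DataFrame:
    """Pair exposure and outcome records on a shared, allele-aligned variant set.

    Variants are matched on (chrom, pos).  If the outcome's alleles are
    swapped relative to the exposure, its beta is negated and eaf replaced by
    1 - eaf; strand flips (allele complements) are reconciled silently.
    Palindromic (A/T, C/G) variants with min(eaf, 1-eaf) above
    ``palindrome_maf_limit`` in either trait are dropped; at or below the
    limit they are aligned by allele frequency.  Unresolvable allele pairs are
    dropped with a reason code.

    Returns a frame with exposure columns suffixed ``_exp`` and outcome
    columns suffixed ``_out`` plus the shared variant identity (exposure
    alleles are authoritative).  Drop counts are in ``.attrs["counts"]``.
    """
    exp = exposure.copy()
    out = outcome.copy()
    exp.attrs = {}
    out.attrs = {}  # stale reader/filter metadata confuses pandas merges
    exp["key"] = exp["chrom"].astype(str) + ":" + exp["pos"].astype(str)
    out["key"] = out["chrom"].astype(str) + ":" + out["pos"].astype(str)
    merged = exp.merge(
        out, on="key", suffixes=("_exp", "_out"), how="inner", validate="1:1"
    )
    counts = {
        "input_exposure": len(exp),
        "input_outcome": len(out),
        "unmatched": len(exp) + len(out) - 2 * len(merged),
    }

    ea_x = merged["ea_exp"].to_numpy()
    oa_x = merged["oa_exp"].to_numpy()
    ea_y = merged["ea_out"].to_numpy()
    oa_y = merged["oa_out"].to_numpy()
    comp = np.vectorize(_COMPLEMENT.get)

    palindromic = np.array(
        [is_strand_ambiguous(a, b) for a, b in zip(ea_x, oa_x)]
    )

    same = (ea_y == ea_x) & (oa_y == oa_x)
    swapped = (ea_y == oa_x) & (oa_y == ea_x)
    if len(merged):
        flip_same = (comp(ea_y) == ea_x) & (comp(oa_y) == oa_x)
        flip_swap = (comp(ea_y) == oa_x) & (comp(oa_y) == ea_x)
    else:  # np.vectorize cannot infer dtype on empty input
        flip_same = flip_swap = np.zeros(0, dtype=bool)

    aligned = same | (~palindromic & flip_same)
    to_swap = swapped | (~palindromic & flip_swap)
    irreconcilable = ~(aligned | to_swap) & ~(palindromic & (swapped | flip_swap))
    # palindromic swap/flip-swap handled by frequency below (letters ambiguous)

    merged.loc[to_swap, "beta_out"] = -merged.loc[to_swap, "beta_out"]
    merged.loc[to_swap, "eaf_out"] = 1.0 - merged.loc[to_swap, "eaf_out"]

    maf_exp = np.minimum(merged["eaf_exp"], 1 - merged["eaf_exp"])
    maf_out = np.minimum(merged["eaf_out"], 1 - merged["eaf_out"])
    drop_palin = palindromic & (
        (maf_exp > palindrome_maf_limit) | (maf_out > palindrome_maf_limit)
    )
    # frequency alignment of retained palindromic variants: effect alleles on
    # the same side of 0.5 in both traits, else flip the outcome
    freq_flip = (
        palindromic
        & ~drop_palin
        & ((merged["eaf_exp"] - 0.5) * (merged["eaf_out"] - 0.5) < 0)
    )
    merged.loc[freq_flip, "beta_out"] = -merged.loc[freq_flip, "beta_out"]
    merged.loc[freq_flip, "eaf_out"] = 1.0 - merged.loc[freq_flip, "eaf_out"]

    keep = ~(drop_palin | irreconcilable)
    counts["palindromic"] = int(drop_palin.sum())
    counts["irreconcilable"] = int(irreconcilable.sum())
    counts["matched"] = int(keep.sum())

    res = merged.loc[keep].copy()
    res = res.rename(
        columns={
            "chrom_exp": "chrom",
            "pos_exp": "pos",
            "rsid_exp": "rsid",
            "ea_exp": "ea",
            "oa_exp": "oa",
        }
    )
    disagree = (res["eaf_exp"] - res["eaf_out"]).abs() > 0.2
    if disagree.any():
        logger.warning(
            "%d variants have exposure/outcome EAF disagreement > 0.2",
            int(disagree.sum()),
        )
    res["eaf"] = res["eaf_exp"]  # exposure frequency is authoritative
    cols = [
        "chrom", "pos", "rsid", "ea", "oa", "eaf",
        "eaf_exp", "beta_exp", "se_exp", "pvalue_exp", "n_exp",
        "eaf_out", "beta_out", "se_out", "pvalue_out", "n_out",
    ]
    res = res[[c for c in cols if c in res.columns]].reset_index(drop=True)
    res.attrs["counts"] = counts
    logger.info("harmonise: %s", counts)
    return res


# ---------------------------------------------------------------------------
# LD


@dataclass
class LDMatrix:
    """Signed pairwise correlation (r) of effect-allele dosages.

    ``variants`` are "chrom:pos" keys in matrix order; the sign convention
    follows each variant's recorded effect allele.
    """

    variants: list[str]
    r: np.ndarray
    source: str = "reference_panel"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (len(self.variants), len(self.variants)):
            raise ValueError("LD matrix shape does not match variant list")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("LD matrix not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-9):
            raise ValueError("LD matrix diagonal must be 1")
        if np.abs(self.r).max() > 1 + 1e-9:
            raise ValueError("|r| exceeds 1")
        self._index = {v: i for i, v in enumerate(self.variants)}

    def submatrix(self, keys) -> "LDMatrix":
        idx = [self._index[k] for k in keys]
        return LDMatrix(list(keys), self.r[np.ix_(idx, idx)], self.source)

    def index_of(self, key: str) -> int:
        return self._index[key]


@dataclass
class ReferencePanel:
    """Phased haplotype panel: rows are haplotypes, columns variants (0/1)."""

    haplotypes: np.ndarray
    variants: pd.DataFrame  # columns chrom, pos, rsid, ea, oa

    def __post_init__(self):
        h = np.asarray(self.haplotypes)
        if not np.isin(h, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        counts = h.sum(axis=0)
        if ((counts == 0) | (counts == h.shape[0])).any():
            raise ValueError("monomorphic columns in reference panel")
        self.haplotypes = h.astype(np.int8)

    @property
    def keys(self) -> list[str]:
        return [
            variant_key(c, p)
            for c, p in zip(self.variants["chrom"], self.variants["pos"])
        ]


def compute_ld(panel: ReferencePanel, subset: pd.DataFrame) -> LDMatrix:
    """Pearson correlation of effect-allele indicator columns for ``subset``.

    ``subset`` needs columns chrom, pos, ea, oa.  A panel column stored on
    the opposite allele is flipped (1 - x) before correlating so signs follow
    the subset's effect alleles.
    """
    panel_keys = {k: i for i, k in enumerate(panel.keys)}
    cols = []
    missing = []
    for _, row in subset.iterrows():
        k = variant_key(row["chrom"], row["pos"])
        if k not in panel_keys:
            missing.append(k)
            continue
        i = panel_keys[k]
        col = panel.haplotypes[:, i].astype(float)
        pea = panel.variants["ea"].iloc[i]
        poa = panel.variants["oa"].iloc[i]
        if row["ea"] == pea and row["oa"] == poa:
            pass
        elif row["ea"] == poa and row["oa"] == pea:
            col = 1.0 - col
        else:
            missing.append(k)
            continue
        cols.append(col)
    if missing:
        raise KeyError(f"variants absent from reference panel: {missing}")
    mat = np.column_stack(cols)
    r = np.corrcoef(mat, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    keys = [variant_key(c, p) for c, p in zip(subset["chrom"], subset["pos"])]
    return LDMatrix(keys, r)


def write_ld(ld: LDMatrix, matrix_path, variants_path) -> None:
    np.savetxt(matrix_path, ld.r, fmt="%.10g", delimiter="\t")
    pd.Series(ld.variants, name="variant").to_csv(variants_path, index=False)


def read_ld(matrix_path, variants_path, source: str = "file") -> LDMatrix:
    r = np.atleast_2d(np.loadtxt(matrix_path, delimiter="\t"))
    variants = pd.read_csv(variants_path)["variant"].tolist()
    return LDMatrix(variants, r, source)


def write_panel(panel: ReferencePanel, haplotype_path, variants_path) -> None:
    np.savetxt(haplotype_path, panel.haplotypes, fmt="%d", delimiter="\t")
    panel.variants.to_csv(variants_path, sep="\t", index=False)


def read_panel(haplotype_path, variants_path) -> ReferencePanel:
    h = np.atleast_2d(np.loadtxt(haplotype_path, delimiter="\t", dtype=np.int8))
    v = pd.read_csv(variants_path, sep="\t")
    return ReferencePanel(h, v)
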