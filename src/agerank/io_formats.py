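"""Readers, writers and the shared site data model.

Coordinate conventions follow the file-format standards: VCF and site
tables are 1-based, BED intervals are 0-based half-open.  All alleles are
reported on the reference forward strand.  Tab-delimited typed tables
(site / age / EP / archaic) carry a one-line header and a deterministic
column order so that writing and re-reading is an exact round trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

SITE_CLASSES = ("nonsynonymous", "noncoding_nonregulatory", "other")
_BASES = frozenset("ACGT")
_MISSING = "."


class FormatError(ValueError):
    """Malformed input file (fatal, reported with line number when known)."""


# ---------------------------------------------------------------------------
# core site model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP.

    ``k`` is the alternate (not necessarily derived) allele count over the
    ``n2`` sampled chromosomes; orientation into ancestral/derived space is
    the job of :mod:`agerank.delta_ep`.  ``ep_ref``/``ep_alt`` are
    evolutionary probabilities in [0, 1] when present.  ``is_cpg`` is None
    when the CpG context is unknown.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    anc_state: str | None = None
    k: int = 0
    n2: int = 2
    ep_ref: float | None = None
    ep_alt: float | None = None
    site_class: str = "other"
    is_cpg: bool | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.n2 <= 0 or self.n2 % 2:
            raise ValueError(f"n2 must be a positive even chromosome count, got {self.n2}")
        if not 0 <= self.k <= self.n2:
            raise ValueError(f"k={self.k} outside [0, n2={self.n2}] at {self.chrom}:{self.pos}")
        for name in ("ep_ref", "ep_alt"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1] at {self.chrom}:{self.pos}")
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site_class {self.site_class!r}")

    @property
    def alt_freq(self) -> float:
        return self.k / self.n2


@dataclass(frozen=True)
class GeneticMap:
    """HapMap-style genetic map: positions (bp), rates (cM/Mb), cumulative cM.

    The rate is piecewise constant: row i's rate applies on
    [pos_i, pos_{i+1}); queries left of the first row take the first rate,
    queries at/after the last row take the last rate.
    """

    positions: np.ndarray
    rates: np.ndarray
    cum_cm: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        rates = np.asarray(self.rates, dtype=float)
        cum = np.asarray(self.cum_cm, dtype=float)
        if pos.size == 0:
            raise FormatError("genetic map is empty")
        if not (pos.size == rates.size == cum.size):
            raise FormatError("genetic map columns have unequal lengths")
        if np.any(np.diff(pos) <= 0):
            bad = int(np.flatnonzero(np.diff(pos) <= 0)[0])
            raise FormatError(f"genetic map positions not strictly increasing at row {bad + 2}")
        if np.any(rates < 0):
            raise FormatError("genetic map has a negative rate")
        if np.any(np.diff(cum) < 0):
            raise FormatError("genetic map cumulative cM is decreasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "cum_cm", cum)

    def rate_at(self, pos):
        """cM/Mb rate at one position or an array of positions."""
        idx = np.searchsorted(self.positions, np.asarray(pos), side="right") - 1
        idx = np.clip(idx, 0, self.positions.size - 1)
        out = self.rates[idx]
        return float(out) if np.ndim(pos) == 0 else out


def rate_at(gmap: GeneticMap, pos):
    """Module-level alias for :meth:`GeneticMap.rate_at`."""
    return gmap.rate_at(pos)


@dataclass(frozen=True)
class ArchaicTable:
    """Alleles observed in >= 1 archaic genome, plus optional introgression intervals.

    ``sites`` holds (chrom, pos, allele) tuples; ``introgression`` maps
    chromosome -> (m, 2) array of 0-based half-open intervals.
    """

    sites: frozenset
    introgression: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, iv in self.introgression.items():
            iv = np.asarray(iv, dtype=np.int64).reshape(-1, 2)
            if np.any(iv[:, 0] >= iv[:, 1]):
                raise FormatError(f"empty/inverted interval on {chrom}")

    def has_allele(self, chrom: str, pos: int, allele: str) -> bool:
        return (chrom, pos, allele) in self.sites

    def in_introgression(self, chrom: str, pos: int) -> bool:
        iv = self.introgression.get(chrom)
        if iv is None or len(iv) == 0:
            return False
        return _point_in_intervals(pos - 1, np.asarray(iv))


def _point_in_intervals(zero_based: int, intervals: np.ndarray) -> bool:
    # intervals sorted by start; point p overlaps [s, e) iff s <= p < e
    starts = intervals[:, 0]
    ends = intervals[:, 1]
    i = np.searchsorted(starts, zero_based, side="right") - 1
    return bool(i >= 0 and zero_based < ends[i])


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_sites(
    path,
    sample_subset: Sequence[str] | None = None,
    site_class: str = "other",
) -> list[SiteRecord]:
    """Read biallelic SNP rows from a VCF into :class:`SiteRecord` objects.

    k is the alternate-allele count over retained samples; n2 counts called
    chromosomes only (a sample with any missing allele contributes nothing,
    so per-site n2 stays even and k/n2 stays unbiased).  Multiallelic rows,
    indels and rows with no called genotypes are skipped with a logged count.
    The ``AA`` INFO key, when present, populates ``anc_state``.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read VCF {path}: {exc}") from exc
    if sample_subset is not None:
        vf.subset_samples(list(sample_subset))
    sites: list[SiteRecord] = []
    skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 or rec.ref is None or len(rec.ref) != 1 or len(alts[0]) != 1 \
                or rec.ref.upper() not in _BASES or alts[0].upper() not in _BASES:
            skipped += 1
            continue
        k = 0
        n2 = 0
        for sample in rec.samples.values():
            gt = sample.get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            n2 += len(gt)
            k += sum(1 for a in gt if a == 1)
        if n2 == 0:
            skipped += 1
            continue
        aa = rec.info.get("AA")
        if isinstance(aa, (tuple, list)):
            aa = aa[0]
        anc = str(aa).upper() if aa not in (None, "", ".") else None
        sites.append(
            SiteRecord(
                chrom=str(rec.chrom),
                pos=int(rec.pos),
                ref_allele=rec.ref.upper(),
                alt_allele=alts[0].upper(),
                anc_state=anc if anc in _BASES else None,
                k=k,
                n2=n2,
                site_class=site_class,
            )
        )
    if skipped:
        logger.info("read_vcf_sites(%s): skipped %d non-biallelic-SNP/uncalled rows", path, skipped)
    return sites


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

def read_genetic_map(path) -> GeneticMap:
    """Parse a whitespace-delimited HapMap-dialect genetic map.

    Accepts either 3 columns (position, rate cM/Mb, cumulative cM) or the
    4-column dialect with a leading chromosome label.  One header line is
    required and skipped.
    """
    rows = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) <= 1:
        raise FormatError(f"genetic map {path} has no data rows")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) == 4:
            parts = parts[1:]
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 or 4 columns, got {len(parts)}")
        try:
            rows.append((int(float(parts[0])), float(parts[1]), float(parts[2])))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise FormatError(f"genetic map {path} has no data rows")
    pos, rates, cum = map(np.asarray, zip(*rows))
    d = np.diff(pos)
    if np.any(d <= 0):
        bad_line = int(np.flatnonzero(d <= 0)[0]) + 3  # +1 header, +1 next row, 1-based
        raise FormatError(f"{path}:{bad_line}: positions not strictly increasing")
    return GeneticMap(pos, rates, cum)


# ---------------------------------------------------------------------------
# BED / filters
# ---------------------------------------------------------------------------

def read_bed(path) -> dict[str, np.ndarray]:
    """Read BED3 into chrom -> sorted, merged (m, 2) interval arrays (0-based half-open)."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED row needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: interval start >= end")
            per_chrom.setdefault(parts[0], []).append((start, end))
    return {c: merge_intervals(np.asarray(iv, dtype=np.int64)) for c, iv in per_chrom.items()}


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/adjacent half-open intervals."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    iv = intervals[np.argsort(intervals[:, 0])]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


def filter_neutral_controls(
    sites: Iterable[SiteRecord],
    regulatory_beds: Sequence[Mapping[str, np.ndarray]],
) -> list[SiteRecord]:
    """Keep only noncoding sites overlapping none of the regulatory interval sets.

    A 1-based site position p overlaps a BED interval [s, e) iff s <= p-1 < e.
    Non-noncoding sites are never control candidates, whatever the intervals.
    """
    out = []
    for site in sites:
        if site.site_class != "noncoding_nonregulatory":
            continue
        hit = False
        for bed in regulatory_beds:
            iv = bed.get(site.chrom)
            if iv is not None and len(iv) and _point_in_intervals(site.pos - 1, np.asarray(iv)):
                hit = True
                break
        if not hit:
            out.append(site)
    return out


def filter_cpg(
    sites: Iterable[SiteRecord],
    reference: Mapping[str, str] | None = None,
) -> list[SiteRecord]:
    """Drop sites in a CpG dinucleotide context.

    An explicit ``is_cpg`` flag wins; otherwise the flag is derived from the
    reference trinucleotide context (C followed by G, or G preceded by C).
    A site with no flag and no reference is fatal.
    """
    out = []
    for site in sites:
        flag = site.is_cpg
        if flag is None:
            if reference is None:
                raise ValueError(f"is_cpg unknown at {site.chrom}:{site.pos} and no reference supplied")
            flag = _cpg_from_reference(site, reference)
            site = replace(site, is_cpg=flag)
        if not flag:
            out.append(site)
    return out


def _cpg_from_reference(site: SiteRecord, reference: Mapping[str, str]) -> bool:
    seq = reference[site.chrom]
    i = site.pos - 1
    base = seq[i].upper()
    nxt = seq[i + 1].upper() if i + 1 < len(seq) else ""
    prv = seq[i - 1].upper() if i > 0 else ""
    return (base == "C" and nxt == "G") or (base == "G" and prv == "C")


# ---------------------------------------------------------------------------
# typed tab-delimited tables
# ---------------------------------------------------------------------------

_SITE_COLUMNS = [
    "chrom", "pos", "ref_allele", "alt_allele", "anc_state", "k", "n2",
    "ep_ref", "ep_alt", "site_class", "is_cpg", "gene_id",
]


def sites_to_frame(sites: Iterable[SiteRecord]) -> pd.DataFrame:
    rows = [{f.name: getattr(s, f.name) for f in fields(SiteRecord)} for s in sites]
    return pd.DataFrame(rows, columns=_SITE_COLUMNS)


def frame_to_sites(df: pd.DataFrame) -> list[SiteRecord]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            SiteRecord(
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref_allele=str(d["ref_allele"]),
                alt_allele=str(d["alt_allele"]),
                anc_state=None if pd.isna(d["anc_state"]) else str(d["anc_state"]),
                k=int(d["k"]),
                n2=int(d["n2"]),
                ep_ref=None if pd.isna(d["ep_ref"]) else float(d["ep_ref"]),
                ep_alt=None if pd.isna(d["ep_alt"]) else float(d["ep_alt"]),
                site_class=str(d["site_class"]),
                is_cpg=None if pd.isna(d["is_cpg"]) else bool(d["is_cpg"]),
                gene_id=None if pd.isna(d["gene_id"]) else str(d["gene_id"]),
            )
        )
    return out


def _write_table(df: pd.DataFrame, path) -> None:
    # default float repr is shortest-round-trip, keeping tables exact
    df.to_csv(path, sep="\t", index=False, na_rep=_MISSING)


def write_site_table(sites: Iterable[SiteRecord], path) -> None:
    df = sites_to_frame(sites).copy()
    df["is_cpg"] = df["is_cpg"].map(lambda v: _MISSING if pd.isna(v) else ("1" if v else "0"))
    _write_table(df, path)


def read_site_table(path) -> list[SiteRecord]:
    df = pd.read_csv(path, sep="\t", na_values=[_MISSING], keep_default_na=False,
                     float_precision="round_trip",
                     dtype={"chrom": str, "gene_id": str, "anc_state": str,
                            "ref_allele": str, "alt_allele": str, "site_class": str})
    missing = set(_SITE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"site table {path} lacks columns: {sorted(missing)}")
    df["is_cpg"] = df["is_cpg"].map(
        lambda v: None if pd.isna(v) else bool(int(v)))
    try:
        return frame_to_sites(df)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"site table {path}: {exc}") from exc


_AGE_COLUMNS = ["chrom", "pos", "estimator", "age_gens"]
AGE_ESTIMATORS = ("tc", "geva", "true")


def validate_age_table(df: pd.DataFrame, source: str = "age table") -> pd.DataFrame:
    """Check age-table invariants: positive ages, known estimator labels, unique keys."""
    missing = set(_AGE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{source} lacks columns: {sorted(missing)}")
    if (df["age_gens"] <= 0).any():
        row = int(df.index[df["age_gens"] <= 0][0]) + 2  # +header, 1-based
        raise FormatError(f"{source}: non-positive age at data row {row}")
    bad = ~df["estimator"].isin(AGE_ESTIMATORS)
    if bad.any():
        raise FormatError(f"{source}: unknown estimator {df.loc[bad, 'estimator'].iloc[0]!r}")
    if df.duplicated(subset=["chrom", "pos", "estimator"]).any():
        dup = df[df.duplicated(subset=["chrom", "pos", "estimator"])].iloc[0]
        raise FormatError(f"{source}: duplicate key ({dup.chrom}, {dup.pos}, {dup.estimator})")
    return df[_AGE_COLUMNS]


def read_age_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={"chrom": str, "estimator": str})
    return validate_age_table(df, source=f"age table {path}")


def write_age_table(df: pd.DataFrame, path) -> None:
    _write_table(validate_age_table(df), path)


_EP_COLUMNS = ["transcript", "pos", "allele", "ep"]


def read_ep_table(path) -> pd.DataFrame:
    """Per-site EP table: transcript, 1-based position, amino-acid/base allele, EP in [0,1]."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript": str, "allele": str})
    missing = set(_EP_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"EP table {path} lacks columns: {sorted(missing)}")
    if ((df["ep"] < 0) | (df["ep"] > 1)).any():
        row = int(df.index[(df["ep"] < 0) | (df["ep"] > 1)][0]) + 2
        raise FormatError(f"EP table {path}: EP outside [0,1] at data row {row}")
    if df.duplicated(subset=["transcript", "pos", "allele"]).any():
        raise FormatError(f"EP table {path}: duplicate (transcript, pos, allele) key")
    return df[_EP_COLUMNS]


def write_ep_table(df: pd.DataFrame, path) -> None:
    _write_table(df[_EP_COLUMNS], path)


def read_archaic_table(path, introgression_bed=None) -> ArchaicTable:
    """Archaic allele table (chrom, pos, allele) plus optional introgression BED."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "allele": str})
    for col in ("chrom", "pos", "allele"):
        if col not in df.columns:
            raise FormatError(f"archaic table {path} lacks column {col!r}")
    sites = frozenset(
        (str(c), int(p), str(a)) for c, p, a in zip(df["chrom"], df["pos"], df["allele"])
    )
    intro = read_bed(introgression_bed) if introgression_bed is not None else {}
    return ArchaicTable(sites=sites, introgression=intro)


def write_archaic_table(table: ArchaicTable, path) -> None:
    df = pd.DataFrame(sorted(table.sites), columns=["chrom", "pos", "allele"])
    _write_table(df, path)
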