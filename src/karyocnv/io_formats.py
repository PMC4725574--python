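"""Readers and writers for the on-disk formats the pipeline touches.

All tabular formats are tab-delimited UTF-8 with a mandatory header row.
In-memory coordinates are 1-based inclusive everywhere; the BED boundary
(0-based half-open) is converted at the I/O boundary and nowhere else.
Chromosome labels are normalized by stripping a leading ``chr`` on read and
emitted bare, except BED export which re-adds the prefix.

Missing LRR/BAF values are encoded as NaN and excluded from every summary
statistic downstream; readers never silently coerce malformed input.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Allowed chromosome labels, in canonical genome order.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")
AUTOSOMES: tuple[str, ...] = CHROMOSOMES[:22]
_CHROM_RANK = {c: i for i, c in enumerate(CHROMOSOMES)}

# copy-number <-> state vocabulary for CNV calls
DELETION_STATES = {0, 1}
DUPLICATION_STATES = {3, 4}
VALID_CN = DELETION_STATES | DUPLICATION_STATES


class FormatError(ValueError):
    """Malformed input; the message names file, line and field."""


def normalize_chrom(raw: str, *, path: str = "<memory>", line: int = 0) -> str:
    label = raw.strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if label == "23":
        label = "X"
    if label not in _CHROM_RANK:
        raise FormatError(
            f"{path}:{line}: field 'chrom': unknown chromosome label {raw!r}"
        )
    return label


def chrom_sort_key(chrom: str) -> int:
    return _CHROM_RANK[chrom]


# ---------------------------------------------------------------------------
# MarkerMap
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Genome-ordered SNP marker coordinate system.

    Markers are sorted by (chromosome, position) on construction; marker ids
    must be unique and positions strictly increasing within a chromosome.
    """

    marker_id: np.ndarray  # object array of str
    chrom: np.ndarray      # object array of canonical labels
    pos: np.ndarray        # int64, 1-based

    _index: dict[str, int] = field(init=False, repr=False)
    _chrom_slices: dict[str, slice] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        order = np.lexsort((self.pos, [ _CHROM_RANK[c] for c in self.chrom ]))
        self.marker_id = self.marker_id[order]
        self.chrom = self.chrom[order]
        self.pos = self.pos[order]
        if len(set(self.marker_id)) != len(self.marker_id):
            counts = pd.Series(self.marker_id).value_counts()
            dup = counts[counts > 1].index[0]
            raise FormatError(f"marker map: field 'marker_id': duplicate id {dup!r}")
        self._chrom_slices = {}
        start = 0
        for i in range(1, len(self.chrom) + 1):
            if i == len(self.chrom) or self.chrom[i] != self.chrom[start]:
                c = self.chrom[start]
                self._chrom_slices[c] = slice(start, i)
                seg = self.pos[start:i]
                if np.any(np.diff(seg) <= 0):
                    raise FormatError(
                        f"marker map: field 'pos': duplicate position on chromosome {c}"
                    )
                start = i
        self._index = {m: i for i, m in enumerate(self.marker_id)}

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_slices)

    def chrom_slice(self, chrom: str) -> slice:
        return self._chrom_slices[chrom]

    def index_of(self, marker: str) -> int:
        return self._index[marker]

    def markers_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices (into the map) of markers on chrom within [start, end]."""
        if chrom not in self._chrom_slices:
            return np.empty(0, dtype=np.int64)
        sl = self._chrom_slices[chrom]
        seg = self.pos[sl]
        lo = int(np.searchsorted(seg, start, side="left"))
        hi = int(np.searchsorted(seg, end, side="right"))
        return np.arange(sl.start + lo, sl.start + hi, dtype=np.int64)

    def n_markers_in(self, chrom: str, start: int, end: int) -> int:
        return len(self.markers_in(chrom, start, end))

    def chrom_span(self, chrom: str) -> tuple[int, int]:
        sl = self._chrom_slices[chrom]
        return int(self.pos[sl][0]), int(self.pos[sl][-1])


def read_marker_map(path: str | Path) -> MarkerMap:
    df = _read_tsv(path, ["marker_id", "chrom", "pos"])
    chroms = [
        normalize_chrom(c, path=str(path), line=i + 2)
        for i, c in enumerate(df["chrom"].astype(str))
    ]
    pos = pd.to_numeric(df["pos"], errors="coerce")
    if pos.isna().any():
        line = int(pos.index[pos.isna()][0]) + 2
        raise FormatError(f"{path}:{line}: field 'pos': non-numeric position")
    return MarkerMap(
        marker_id=df["marker_id"].astype(str).to_numpy(dtype=object),
        chrom=np.asarray(chroms, dtype=object),
        pos=pos.astype(np.int64).to_numpy(),
    )


def write_marker_map(mmap: MarkerMap, path: str | Path) -> None:
    pd.DataFrame(
        {"marker_id": mmap.marker_id, "chrom": mmap.chrom, "pos": mmap.pos}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# IntensityProfile
# ---------------------------------------------------------------------------


@dataclass
class IntensityProfile:
    """One sample's LRR and BAF vectors aligned to a MarkerMap.

    Missing measurements are NaN; ``lrr_mask``/``baf_mask`` expose the
    observed-marker masks used by all downstream summaries.
    """

    sample_id: str
    lrr: np.ndarray
    baf: np.ndarray
    map_ref: MarkerMap

    def __post_init__(self) -> None:
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.baf = np.asarray(self.baf, dtype=float)
        n = len(self.map_ref)
        if len(self.lrr) != n or len(self.baf) != n:
            raise ValueError(
                f"profile {self.sample_id}: lrr/baf length != map length {n}"
            )
        with np.errstate(invalid="ignore"):
            self.baf = np.clip(self.baf, 0.0, 1.0)

    @property
    def lrr_mask(self) -> np.ndarray:
        return ~np.isnan(self.lrr)

    @property
    def baf_mask(self) -> np.ndarray:
        return ~np.isnan(self.baf)


def read_intensity(path: str | Path, mmap: MarkerMap) -> list[IntensityProfile]:
    """Read a long-format intensity TSV into map-aligned profiles.

    Markers absent from the map are a hard error; markers absent from the
    file are NaN (missing) in the profile. Duplicate (sample, marker) rows
    are rejected.
    """
    df = _read_tsv(path, ["sample_id", "marker_id", "lrr", "baf"])
    unknown = ~df["marker_id"].astype(str).isin(mmap._index)
    if unknown.any():
        line = int(df.index[unknown][0]) + 2
        bad = df["marker_id"][unknown].iloc[0]
        raise FormatError(
            f"{path}:{line}: field 'marker_id': marker {bad!r} not in map"
        )
    for col in ("lrr", "baf"):
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & ~raw.astype(str).str.strip().str.upper().isin(
            {"NA", "NAN", ""}
        )
        if bad.any():
            line = int(raw.index[bad][0]) + 2
            raise FormatError(
                f"{path}:{line}: field '{col}': non-numeric value {raw[bad].iloc[0]!r}"
            )
        df[col] = num
    dup = df.duplicated(subset=["sample_id", "marker_id"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        s, m = df.loc[df.index[dup][0], ["sample_id", "marker_id"]]
        raise FormatError(
            f"{path}:{line}: duplicate row for sample {s!r}, marker {m!r}"
        )
    profiles = []
    n = len(mmap)
    for sid, grp in df.groupby("sample_id", sort=True):
        lrr = np.full(n, np.nan)
        baf = np.full(n, np.nan)
        idx = [mmap.index_of(m) for m in grp["marker_id"].astype(str)]
        lrr[idx] = grp["lrr"].to_numpy()
        baf[idx] = grp["baf"].to_numpy()
        profiles.append(IntensityProfile(str(sid), lrr, baf, mmap))
    return profiles


def write_intensity(
    profiles: Iterable[IntensityProfile], path: str | Path, decimals: int = 6
) -> None:
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": p.sample_id,
                    "marker_id": p.map_ref.marker_id,
                    "lrr": np.round(p.lrr, decimals),
                    "baf": np.round(p.baf, decimals),
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# CNV calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    cn: int
    n_markers: int
    algorithm: str
    score: float = float("nan")

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(
                f"CNV call {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "field 'end': end < start"
            )
        if self.cn not in VALID_CN:
            raise FormatError(
                f"CNV call {self.sample_id}: field 'cn': copy number {self.cn} "
                "not in {0,1,3,4}"
            )
        if self.n_markers < 1:
            raise FormatError(
                f"CNV call {self.sample_id}: field 'n_markers': must be >= 1"
            )

    @property
    def state(self) -> str:
        return "deletion" if self.cn in DELETION_STATES else "duplication"

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


_PENN_RE = re.compile(
    r"^chr(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+length=(?P<length>[\d,]+)\s+"
    r"state\d,cn=(?P<cn>\d+)\s+(?P<sample>\S+)"
    r"(?:\s+startsnp=\S+\s+endsnp=\S+)?(?:\s+conf=(?P<conf>\S+))?\s*$"
)


def read_cnv_calls(path: str | Path, dialect: str) -> list[CnvCall]:
    """Read a per-algorithm CNV call file; dialect must be declared.

    ``pennCNV_like`` is whitespace-delimited caller text
    (``chr1:1000-5000 numsnp=12 length=4001 state2,cn=1 sample ...``);
    ``canonical_tsv`` is this package's own tab-delimited interchange format.
    """
    if dialect == "pennCNV_like":
        return _read_penncnv(path)
    if dialect == "canonical_tsv":
        return _read_canonical_cnv(path)
    raise ValueError(f"unknown CNV dialect {dialect!r}")


def _read_penncnv(path: str | Path) -> list[CnvCall]:
    calls = []
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            m = _PENN_RE.match(raw)
            if m is None:
                raise FormatError(f"{path}:{ln}: unparseable pennCNV-like line")
            cn = int(m.group("cn"))
            if cn not in VALID_CN:
                raise FormatError(
                    f"{path}:{ln}: field 'cn': state token cn={cn} unknown"
                )
            sample = m.group("sample")
            # caller text often carries a filename; strip a trailing extension
            sample = re.sub(r"\.(txt|tsv)$", "", sample)
            try:
                calls.append(
                    CnvCall(
                        sample_id=sample,
                        chrom=normalize_chrom(m.group("chrom"), path=str(path), line=ln),
                        start=int(m.group("start")),
                        end=int(m.group("end")),
                        cn=cn,
                        n_markers=int(m.group("numsnp")),
                        algorithm="pennCNV_like",
                        score=float(m.group("conf")) if m.group("conf") else math.nan,
                    )
                )
            except FormatError as e:
                raise FormatError(f"{path}:{ln}: {e}") from None
    return calls


_CANONICAL_CNV_COLS = [
    "sample_id", "chrom", "start", "end", "cn", "n_markers", "algorithm", "score",
]


def _read_canonical_cnv(path: str | Path) -> list[CnvCall]:
    df = _read_tsv(path, _CANONICAL_CNV_COLS)
    calls = []
    for i, row in df.iterrows():
        ln = int(i) + 2
        try:
            cn = int(row["cn"])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}:{ln}: field 'cn': unknown state token {row['cn']!r}"
            ) from None
        try:
            calls.append(
                CnvCall(
                    sample_id=str(row["sample_id"]),
                    chrom=normalize_chrom(str(row["chrom"]), path=str(path), line=ln),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    cn=cn,
                    n_markers=int(row["n_markers"]),
                    algorithm=str(row["algorithm"]),
                    score=float(row["score"]),
                )
            )
        except FormatError as e:
            raise FormatError(f"{path}:{ln}: {e}") from None
    return calls


def write_cnv_calls(calls: Sequence[CnvCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "cn": c.cn,
                "n_markers": c.n_markers,
                "algorithm": c.algorithm,
                "score": round(c.score, 6) if not math.isnan(c.score) else "NA",
            }
            for c in calls
        ],
        columns=_CANONICAL_CNV_COLS,
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Region sets (BED4)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int  # 1-based inclusive in memory
    end: int
    label: str

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionSet:
    name: str
    regions: list[Region]

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


def read_regions_bed(path: str | Path, name: str | None = None) -> RegionSet:
    """Read a 4-column BED file; 0-based half-open becomes 1-based inclusive."""
    regions = []
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: BED4 requires 4 columns")
            chrom = normalize_chrom(parts[0], path=str(path), line=ln)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{ln}: field 'start'/'end': non-integer coordinate"
                ) from None
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{ln}: field 'start': requires 0 <= start < end"
                )
            if not parts[3].strip():
                raise FormatError(f"{path}:{ln}: field 'name': empty label")
            regions.append(Region(chrom, start + 1, end, parts[3].strip()))
    return RegionSet(name=name or Path(path).stem, regions=regions)


def write_regions_bed(rset: RegionSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in rset:
            fh.write(f"chr{r.chrom}\t{r.start - 1}\t{r.end}\t{r.label}\n")


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

PHENOTYPES = [
    "age_of_onset",
    "duration_worst_episode",
    "neuroticism",
    "extraversion",
    "psychoticism",
]
COHORTS = ("case", "screened_control", "population_control")
_PHENO_COLS = ["sample_id", "sex", "cohort"] + PHENOTYPES


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV -> DataFrame indexed by sample_id; missing stays NaN."""
    df = _read_tsv(path, _PHENO_COLS)
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: field 'sample_id': duplicate id {dup!r}")
    bad_sex = ~df["sex"].isin(["male", "female"])
    if bad_sex.any():
        line = int(df.index[bad_sex][0]) + 2
        raise FormatError(
            f"{path}:{line}: field 'sex': value {df['sex'][bad_sex].iloc[0]!r}"
        )
    bad_cohort = ~df["cohort"].isin(COHORTS)
    if bad_cohort.any():
        line = int(df.index[bad_cohort][0]) + 2
        raise FormatError(
            f"{path}:{line}: field 'cohort': value {df['cohort'][bad_cohort].iloc[0]!r}"
        )
    for col in PHENOTYPES:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & ~raw.astype(str).str.strip().str.upper().isin(
            {"NA", "NAN", ""}
        )
        if bad.any():
            line = int(raw.index[bad][0]) + 2
            raise FormatError(
                f"{path}:{line}: field '{col}': non-numeric value {raw[bad].iloc[0]!r}"
            )
        df[col] = num
    return df.set_index("sample_id")


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    out = df.reset_index() if df.index.name == "sample_id" else df.copy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA",
               columns=_PHENO_COLS, float_format="%.6g")


# ---------------------------------------------------------------------------
# shared TSV plumbing
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}:1: empty file, header row required") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}:1: header missing column(s) {missing}")
    df = df.replace({"NA": np.nan, "": np.nan})
    return df
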