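"""Genotype-count monitoring tables: parsing, validation and descriptive statistics.

The observed unit is a per-room, per-monitoring-point triple of genotype counts
(WT/WT, WT/ko, ko/ko), optionally split by sex and tagged by cohort.  From these
the module derives WT allele frequencies, a one-degree-of-freedom Pearson
chi-square test of Hardy--Weinberg proportions, cumulative per-room summaries,
and the ordered frequency vectors used as ABC summary statistics.
"""
from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    DataFormatError,
    DegenerateTestError,
    ValidationError,
)

Triple = tuple[int, int, int]

#: canonical genotype order everywhere in the package
GENOTYPE_ORDER = ("wt_hom", "het", "ko_hom")

REQUIRED_COLUMNS = ("room", "time_point", "n_wt_hom", "n_het", "n_ko_hom")


@dataclasses.dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts at one room/monitoring point.

    ``sex_split``, when present, is a ``(female, male)`` pair of count triples
    that must sum to the unsplit triple.
    """

    room_id: str
    time_point: int
    n_wt_hom: int
    n_het: int
    n_ko_hom: int
    sex_split: tuple[Triple, Triple] | None = None
    cohort: str | None = None

    def __post_init__(self) -> None:
        if self.time_point < 0:
            raise ValidationError(f"negative time point {self.time_point}")
        for name in ("n_wt_hom", "n_het", "n_ko_hom"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(
                    f"{self.room_id} t={self.time_point}: {name}={v!r} is not a "
                    "non-negative integer"
                )
        if self.sex_split is not None:
            f, m = self.sex_split
            if tuple(a + b for a, b in zip(f, m)) != self.triple:
                raise ValidationError(
                    f"{self.room_id} t={self.time_point}: sex-split triples "
                    f"{f}+{m} do not sum to {self.triple}"
                )

    @property
    def triple(self) -> Triple:
        return (self.n_wt_hom, self.n_het, self.n_ko_hom)

    @property
    def n_total(self) -> int:
        return self.n_wt_hom + self.n_het + self.n_ko_hom


@dataclasses.dataclass(frozen=True)
class FrequencySummary:
    """Derived frequencies and HWE statistic for one pool of counts."""

    f_wt: float
    f_ko: float
    genotype_freqs: tuple[float, float, float]
    chi2_hwe: float
    n_total: int


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    if dialect is not None:
        raise DataFormatError(f"unknown dialect {dialect!r}")
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_counts(path: str | Path, dialect: str | None = None) -> list[GenotypeCounts]:
    """Read a genotype-count monitoring table (CSV/TSV by extension).

    Required columns: room, time_point, n_wt_hom, n_het, n_ko_hom.
    Optional columns: sex (``F``/``M``; rows are merged per room/point/cohort
    into records carrying a ``sex_split``), cohort.
    """
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing column(s) {missing}")

    def parse_count(row_no: int, col: str, raw: str) -> int:
        try:
            v = int(raw)
        except (TypeError, ValueError):
            raise ValidationError(f"{path} row {row_no}: {col}={raw!r} is not an integer")
        if v < 0:
            raise ValidationError(f"{path} row {row_no}: {col}={v} is negative")
        return v

    has_sex = "sex" in df.columns
    has_cohort = "cohort" in df.columns
    rows: list[dict] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        rec = row._asdict()
        rows.append(
            {
                "room": str(rec["room"]),
                "time_point": parse_count(i, "time_point", rec["time_point"]),
                "triple": tuple(
                    parse_count(i, c, rec[c]) for c in ("n_wt_hom", "n_het", "n_ko_hom")
                ),
                "sex": str(rec["sex"]).upper() if has_sex else None,
                "cohort": (
                    str(rec["cohort"])
                    if has_cohort and not pd.isna(rec["cohort"])
                    else None
                ),
            }
        )

    if not has_sex:
        return [
            GenotypeCounts(r["room"], r["time_point"], *r["triple"], cohort=r["cohort"])
            for r in rows
        ]

    # merge per-sex rows into one record per (room, time point, cohort)
    out: list[GenotypeCounts] = []
    keys: list[tuple] = []
    by_key: dict[tuple, dict[str, Triple]] = {}
    for r in rows:
        key = (r["room"], r["time_point"], r["cohort"])
        if key not in by_key:
            by_key[key] = {}
            keys.append(key)
        if r["sex"] not in {"F", "M"}:
            raise ValidationError(f"unknown sex label {r['sex']!r} in {path}")
        if r["sex"] in by_key[key]:
            raise ValidationError(f"duplicate sex row for {key} in {path}")
        by_key[key][r["sex"]] = r["triple"]
    for key in keys:
        room, tp, cohort = key
        f = by_key[key].get("F", (0, 0, 0))
        m = by_key[key].get("M", (0, 0, 0))
        total = tuple(a + b for a, b in zip(f, m))
        out.append(
            GenotypeCounts(room, tp, *total, sex_split=(f, m), cohort=cohort)
        )
    return out


def write_counts(records: Iterable[GenotypeCounts], path: str | Path) -> None:
    """Write records in the format :func:`read_counts` accepts (round-trips)."""
    path = Path(path)
    sep = _sep_for(path, None)
    rows = []
    for rec in records:
        if rec.sex_split is not None:
            for sex, triple in zip("FM", rec.sex_split):
                rows.append(
                    dict(
                        room=rec.room_id,
                        time_point=rec.time_point,
                        sex=sex,
                        cohort=rec.cohort,
                        n_wt_hom=triple[0],
                        n_het=triple[1],
                        n_ko_hom=triple[2],
                    )
                )
        else:
            rows.append(
                dict(
                    room=rec.room_id,
                    time_point=rec.time_point,
                    cohort=rec.cohort,
                    n_wt_hom=rec.n_wt_hom,
                    n_het=rec.n_het,
                    n_ko_hom=rec.n_ko_hom,
                )
            )
    df = pd.DataFrame(rows)
    if df["cohort"].isna().all():
        df = df.drop(columns=["cohort"])
    df.to_csv(path, sep=sep, index=False)


def allele_frequency(counts: GenotypeCounts | Triple) -> float:
    """WT allele frequency (2*n_wt_hom + n_het) / 2N."""
    a, b, c = counts.triple if isinstance(counts, GenotypeCounts) else counts
    n = a + b + c
    if n == 0:
        raise DegenerateTestError("allele frequency undefined for N = 0")
    return (2 * a + b) / (2 * n)


def hwe_chi_square(counts: GenotypeCounts | Triple) -> float:
    """Pearson chi-square of the three genotype classes against HWE.

    Expectations are N*p^2, 2Npq, N*q^2 with p estimated from the same sample;
    one degree of freedom, no continuity correction.
    """
    triple = counts.triple if isinstance(counts, GenotypeCounts) else tuple(counts)
    p = allele_frequency(triple)
    if not 0.0 < p < 1.0:
        raise DegenerateTestError("HWE test undefined for a monomorphic sample")
    n = sum(triple)
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.asarray(triple, dtype=float)
    return float(((observed - expected) ** 2 / expected).sum())


def hwe_p_value(counts: GenotypeCounts | Triple) -> float:
    """Upper-tail p-value of :func:`hwe_chi_square` on 1 df."""
    return float(stats.chi2.sf(hwe_chi_square(counts), df=1))


def summarize(counts: GenotypeCounts | Triple) -> FrequencySummary:
    triple = counts.triple if isinstance(counts, GenotypeCounts) else tuple(counts)
    n = sum(triple)
    f_wt = allele_frequency(triple)
    freqs = tuple(x / n for x in triple)
    try:
        chi2 = hwe_chi_square(triple)
    except DegenerateTestError:
        chi2 = float("nan")
    return FrequencySummary(f_wt, 1.0 - f_wt, freqs, chi2, n)


def cumulative_summary(
    records: Sequence[GenotypeCounts],
    exclude_cohorts: Sequence[str] = ("F0",),
) -> pd.DataFrame:
    """Per-room cumulative genotype totals with f_WT, f_ko and HWE chi-square.

    Counts are summed over all time points per room; records whose cohort is in
    ``exclude_cohorts`` (founders by default) are left out of the totals.
    """
    if not records:
        warnings.warn("cumulative_summary: empty input", stacklevel=2)
        return pd.DataFrame(
            columns=["room", "n", "n_wt_hom", "n_het", "n_ko_hom", "chi2", "f_wt", "f_ko"]
        )
    totals: dict[str, np.ndarray] = {}
    for rec in records:
        if rec.cohort is not None and rec.cohort in exclude_cohorts:
            continue
        totals.setdefault(rec.room_id, np.zeros(3, dtype=int))
        totals[rec.room_id] += np.array(rec.triple)
    rows = []
    for room in sorted(totals):
        triple = tuple(int(x) for x in totals[room])
        s = summarize(triple)
        rows.append(
            dict(
                room=room,
                n=s.n_total,
                n_wt_hom=triple[0],
                n_het=triple[1],
                n_ko_hom=triple[2],
                chi2=s.chi2_hwe,
                f_wt=s.f_wt,
                f_ko=s.f_ko,
            )
        )
    return pd.DataFrame(rows)


def format_summary_table(summary: pd.DataFrame) -> str:
    """Human-readable cumulative report (frequencies and chi-square to 2 dp)."""
    df = summary.copy()
    for col in ("chi2", "f_wt", "f_ko"):
        df[col] = df[col].map(lambda v: f"{v:.2f}")
    return df.to_string(index=False)


def observation_vector(
    records: Sequence[GenotypeCounts],
    mode: Literal["A", "G"],
    start_time: int = 0,
) -> np.ndarray:
    """Ordered ABC observation vector from monitoring records.

    Mode ``A``: WT allele frequency per room/time point.  Mode ``G``: the three
    genotype frequencies per room/time point.  Ordering is frozen: rooms in
    ascending id, time points ascending, genotypes (WT/WT, HET, ko/ko).  Time
    points before ``start_time`` are excluded.  Records sharing a room/time
    point (e.g. per-cohort rows) are pooled.
    """
    if mode not in {"A", "G"}:
        raise ValueError(f"mode must be 'A' or 'G', got {mode!r}")
    pooled: dict[tuple[str, int], np.ndarray] = {}
    for rec in records:
        if rec.time_point < start_time:
            continue
        key = (rec.room_id, rec.time_point)
        pooled.setdefault(key, np.zeros(3, dtype=int))
        pooled[key] += np.array(rec.triple)
    rooms = sorted({room for room, _ in pooled})
    if not rooms:
        raise AlignmentError(f"no records at or after start_time={start_time}")
    grids = {room: sorted(t for r, t in pooled if r == room) for room in rooms}
    ref = grids[rooms[0]]
    for room, grid in grids.items():
        if grid != ref:
            missing = sorted(set(ref).symmetric_difference(grid))
            raise AlignmentError(
                f"ragged time grids: room {room} differs at points {missing}"
            )
    out: list[float] = []
    for room in rooms:
        for t in ref:
            triple = pooled[(room, t)]
            n = int(triple.sum())
            if n == 0:
                raise AlignmentError(f"zero total count at room {room}, t={t}")
            if mode == "A":
                out.append((2 * triple[0] + triple[1]) / (2 * n))
            else:
                out.extend(triple / n)
    return np.asarray(out, dtype=float)
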