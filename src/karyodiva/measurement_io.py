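"""Reading, validation and reporting of chromosome measurement tables.

The on-disk measurement format is a UTF-8 CSV with header columns
``plate_id, chromosome_id, short_arm_um, long_arm_um`` (lengths in
micrometres); lines starting with ``#`` are comments.  Each plate is one
photographed metaphase: it must carry an even number of chromosomes
(homologs come in pairs) and every plate in a table must carry the same
number (they are spreads of the same complement).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ChromosomeMeasurement",
    "MeasurementTable",
    "MeasurementError",
    "read_measurements",
    "write_measurements",
    "write_summary_report",
    "REPORT_ROW_LABELS",
]

COLUMNS = ("plate_id", "chromosome_id", "short_arm_um", "long_arm_um")


class MeasurementError(ValueError):
    """Malformed or invalid measurement input."""


@dataclass(frozen=True)
class ChromosomeMeasurement:
    """One measured chromosome on one metaphase plate.

    After ingest normalization ``short_arm <= long_arm``; both arms are
    strictly positive micrometre lengths.
    """

    plate_id: str
    chromosome_id: str
    short_arm: float
    long_arm: float

    @property
    def total_length(self) -> float:
        return self.short_arm + self.long_arm

    @property
    def centromeric_index(self) -> float:
        """Short arm as a percentage of total chromosome length."""
        return 100.0 * self.short_arm / (self.short_arm + self.long_arm)

    @property
    def arm_ratio(self) -> float:
        return self.long_arm / self.short_arm


@dataclass
class MeasurementTable:
    """An ordered collection of measurements from one organism's plates."""

    measurements: list[ChromosomeMeasurement]

    def plate_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for m in self.measurements:
            census[m.plate_id] = census.get(m.plate_id, 0) + 1
        return census

    def plates(self) -> dict[str, list[ChromosomeMeasurement]]:
        """Measurements grouped by plate, preserving row order."""
        by_plate: dict[str, list[ChromosomeMeasurement]] = {}
        for m in self.measurements:
            by_plate.setdefault(m.plate_id, []).append(m)
        return by_plate

    def validate(self) -> None:
        if not self.measurements:
            raise MeasurementError("measurement table is empty")
        census = self.plate_census()
        counts = set(census.values())
        for plate, count in census.items():
            if count < 2 or count % 2 != 0:
                raise MeasurementError(
                    f"plate {plate!r} has {count} chromosomes; "
                    "an even count >= 2 is required for homolog pairing"
                )
        if len(counts) > 1:
            raise MeasurementError(
                f"plates disagree on chromosome count: {sorted(census.items())}"
            )
        for m in self.measurements:
            if m.short_arm <= 0 or m.long_arm <= 0:
                raise MeasurementError(
                    f"nonpositive arm length for chromosome {m.chromosome_id!r} "
                    f"on plate {m.plate_id!r}"
                )


def read_measurements(path, swap_policy: str = "auto_orient") -> MeasurementTable:
    """Read a measurement CSV into a validated :class:`MeasurementTable`.

    ``swap_policy='auto_orient'`` silently swaps arms so that
    ``short_arm <= long_arm`` (arm identity is unordered when measuring
    from a micrograph); ``'strict'`` raises on short > long.
    """
    if swap_policy not in ("auto_orient", "strict"):
        raise ValueError(f"unknown swap_policy {swap_policy!r}")
    try:
        df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except Exception as exc:  # pandas raises several parser error types
        raise MeasurementError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise MeasurementError(f"{path}: missing columns {missing}")

    measurements: list[ChromosomeMeasurement] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        plate = str(getattr(row, "plate_id"))
        chrom = str(getattr(row, "chromosome_id"))
        try:
            short = float(getattr(row, "short_arm_um"))
            long = float(getattr(row, "long_arm_um"))
        except (TypeError, ValueError) as exc:
            raise MeasurementError(f"{path}: malformed row at line {idx}: {exc}") from exc
        if short != short or long != long:  # NaN from empty field
            raise MeasurementError(f"{path}: malformed row at line {idx}: empty length")
        if short > long:
            if swap_policy == "strict":
                raise MeasurementError(
                    f"{path}: line {idx}: short_arm {short} > long_arm {long} "
                    "under strict policy"
                )
            short, long = long, short
        measurements.append(ChromosomeMeasurement(plate, chrom, short, long))

    seen: set[tuple[str, str]] = set()
    for m in measurements:
        key = (m.plate_id, m.chromosome_id)
        if key in seen:
            raise MeasurementError(
                f"duplicate chromosome_id {m.chromosome_id!r} on plate {m.plate_id!r}"
            )
        seen.add(key)

    table = MeasurementTable(measurements)
    table.validate()
    return table


def write_measurements(table: MeasurementTable, path) -> None:
    """Write a measurement table as CSV (4 decimal places, round-trip safe)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(COLUMNS) + "\n")
        for m in table.measurements:
            fh.write(
                f"{m.plate_id},{m.chromosome_id},{m.short_arm:.4f},{m.long_arm:.4f}\n"
            )


# Row labels of the comparative karyotype report, in presentation order.
REPORT_ROW_LABELS = (
    "2n",
    "Total haploid chromosome length (THCL ± SE (µm))",
    "Haploid karyotype formula",
    "Coefficient of Variation of Chromosome Length (CVCL)",
    "Coefficient of Variation of Centromeric Index (CVCI)",
    "Mean Centromeric Asymmetry (MCA)",
    "Shortest chromosome (S ± SE (µm))",
    "Longest chromosome (L ± SE (µm))",
    "Mean chromosome length (MCL ± SE (µm))",
    "Longest to shortest chromosome ratio (R)",
    "Stebbins category (St)",
)


def _fmt(value: float) -> str:
    return f"{value:.2f}"


def _summary_column(summary) -> list[str]:
    """Format one KaryotypeSummary into report cell values (2 d.p.)."""
    return [
        str(summary.diploid_number),
        f"{_fmt(summary.thcl)} ± {_fmt(summary.thcl_se)}",
        summary.formula,
        _fmt(summary.cv_cl),
        _fmt(summary.cv_ci),
        _fmt(summary.m_ca),
        f"{_fmt(summary.shortest)} ± {_fmt(summary.shortest_se)}",
        f"{_fmt(summary.longest)} ± {_fmt(summary.longest_se)}",
        f"{_fmt(summary.mcl)} ± {_fmt(summary.mcl_se)}",
        _fmt(summary.ratio_r),
        summary.stebbins,
    ]


def write_summary_report(summaries: Sequence, path, names: Iterable[str] | None = None,
                         fmt: str = "tsv") -> None:
    """Emit a comparative karyotype table for one or more summaries.

    ``fmt='tsv'`` writes tab-separated values; ``fmt='text'`` writes a
    plain-text column-aligned table.  Columns appear in the order given.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("at least one karyotype summary is required")
    if fmt not in ("tsv", "text"):
        raise ValueError(f"unknown report format {fmt!r}")
    names = list(names) if names is not None else [
        f"karyotype_{i + 1}" for i in range(len(summaries))
    ]
    if len(names) != len(summaries):
        raise ValueError("one column name per summary is required")

    columns = [_summary_column(s) for s in summaries]
    rows = [("Parameter", *names)]
    for i, label in enumerate(REPORT_ROW_LABELS):
        rows.append((label, *(col[i] for col in columns)))

    buf = io.StringIO()
    if fmt == "tsv":
        for row in rows:
            buf.write("\t".join(row) + "\n")
    else:
        widths = [max(len(r[i]) for r in rows) for i in range(len(rows[0]))]
        for row in rows:
            buf.write("  ".join(c.ljust(w) for c, w in zip(row, widths)).rstrip() + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
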