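"""FreeSurfer-style morphometry ingestion and eTIV normalization.

Reads the plain-text ``aseg.stats`` / ``aparc.stats`` dialect (``#`` comment
lines, a ``# Measure EstimatedTotalIntraCranialVol`` header carrying the
eTIV, whitespace-delimited data rows) and converts regional volumes to
percentages of the estimated total intracranial volume so that head-size
differences do not masquerade as atrophy. Thickness and surface area are
passed through unnormalized.

Feature naming: ``Vol%:<hemi>_<region>``, ``Thick:<...>``, ``Area:<...>``
with lowercase region names and ``lh_``/``rh_`` hemisphere prefixes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import pandas as pd

from .errors import StatsParseError

logger = logging.getLogger(__name__)

__all__ = ["MorphometryRecord", "parse_stats_table", "etiv_normalize",
           "write_stats_table"]

MEASURES = ("volume", "thickness", "area")
_MEASURE_PREFIX = {"volume": "Vol%", "thickness": "Thick", "area": "Area"}


@dataclass
class MorphometryRecord:
    """One region × measure morphometry value."""

    region: str          # canonical: lowercase, lh_/rh_ prefix (or bare for midline)
    measure: str         # volume (mm^3) | thickness (mm) | area (mm^2)
    value: float
    etiv: float          # mm^3, shared across a subject's records

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise StatsParseError(f"unknown measure {self.measure!r}")
        if self.value <= 0:
            raise StatsParseError(
                f"{self.measure} of {self.region!r} must be positive, got {self.value}")
        if self.etiv <= 0:
            raise StatsParseError(f"eTIV must be positive, got {self.etiv}")


def canonical_region(name: str, hemisphere: str | None = None) -> str:
    """Lowercase region name with a stable hemisphere prefix."""
    name = name.strip().lower().replace("-", "_")
    name = re.sub(r"^(left_|lh_)", "lh_", name)
    name = re.sub(r"^(right_|rh_)", "rh_", name)
    if hemisphere in ("lh", "rh") and not name.startswith(("lh_", "rh_")):
        name = f"{hemisphere}_{name}"
    return name


_ETIV_RE = re.compile(
    r"#\s*Measure\s+EstimatedTotalIntraCranialVol\b.*?,\s*([0-9.eE+]+)\s*,\s*mm\^3")


def parse_stats_table(stream: TextIO | Iterable[str],
                      dialect: str = "aseg") -> list[MorphometryRecord]:
    """Parse an aseg/aparc-style stats table into morphometry records.

    ``dialect='aseg'`` expects subcortical rows ``<region> <volume_mm3>``;
    ``dialect='aparc'`` expects cortical rows
    ``<region> <area_mm2> <volume_mm3> <thickness_mm>`` with the hemisphere
    declared in a ``# hemi <lh|rh>`` header. Comment lines start with ``#``;
    the eTIV comes from the ``Measure EstimatedTotalIntraCranialVol`` line
    and is mandatory. Malformed rows raise with their line number.
    """
    if dialect not in ("aseg", "aparc"):
        raise StatsParseError(f"unknown dialect {dialect!r}")
    lines = stream.read().splitlines() if hasattr(stream, "read") else list(stream)
    etiv = None
    hemi = None
    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            m = _ETIV_RE.search(line)
            if m:
                etiv = float(m.group(1))
            hm = re.search(r"#\s*hemi\s+(lh|rh)\b", line)
            if hm:
                hemi = hm.group(1)
            continue
        rows.append((lineno, line.split()))
    if etiv is None:
        raise StatsParseError("eTIV not found (no EstimatedTotalIntraCranialVol line)")

    records: list[MorphometryRecord] = []
    for lineno, parts in rows:
        try:
            if dialect == "aseg":
                if len(parts) < 2:
                    raise ValueError("expected <region> <volume>")
                region = canonical_region(parts[0])
                records.append(MorphometryRecord(region, "volume", float(parts[1]), etiv))
                if len(parts) > 2:
                    logger.info("line %d: ignoring %d extra columns", lineno, len(parts) - 2)
            else:
                if len(parts) < 4:
                    raise ValueError("expected <region> <area> <volume> <thickness>")
                region = canonical_region(parts[0], hemisphere=hemi)
                records.append(MorphometryRecord(region, "area", float(parts[1]), etiv))
                records.append(MorphometryRecord(region, "volume", float(parts[2]), etiv))
                records.append(MorphometryRecord(region, "thickness", float(parts[3]), etiv))
                if len(parts) > 4:
                    logger.info("line %d: ignoring %d extra columns", lineno, len(parts) - 4)
        except (ValueError, StatsParseError) as exc:
            raise StatsParseError(f"line {lineno}: {exc}") from exc
    return records


def etiv_normalize(records: Sequence[MorphometryRecord]) -> pd.Series:
    """Regional features with volumes as percentages of eTIV.

    ``Vol%:<region> = 100 * volume / eTIV``; thickness and area pass
    through unchanged under ``Thick:`` / ``Area:`` names.
    """
    if not records:
        raise StatsParseError("no morphometry records to normalize")
    feats = {}
    for rec in records:
        name = f"{_MEASURE_PREFIX[rec.measure]}:{rec.region}"
        if rec.measure == "volume":
            feats[name] = 100.0 * rec.value / rec.etiv
        else:
            feats[name] = rec.value
    return pd.Series(feats)


def write_stats_table(records: Sequence[MorphometryRecord], path,
                      dialect: str = "aseg", hemi: str | None = None) -> None:
    """Write records in the stats-table dialect that `parse_stats_table` reads.

    Used by the cohort simulator so the parser can be round-trip tested.
    """
    if not records:
        raise StatsParseError("nothing to write")
    etiv = records[0].etiv
    lines = ["# Title synthetic morphometry stats",
             f"# Measure EstimatedTotalIntraCranialVol, eTIV, "
             f"Estimated Total Intracranial Volume, {etiv:.6f}, mm^3"]
    if dialect == "aparc":
        lines.append(f"# hemi {hemi or 'lh'}")
        by_region: dict[str, dict[str, float]] = {}
        for rec in records:
            by_region.setdefault(rec.region, {})[rec.measure] = rec.value
        for region, vals in by_region.items():
            name = re.sub(r"^(lh_|rh_)", "", region)
            lines.append(f"{name} {vals['area']:.6f} {vals['volume']:.6f} "
                         f"{vals['thickness']:.6f}")
    else:
        for rec in records:
            if rec.measure == "volume":
                lines.append(f"{rec.region} {rec.value:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
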