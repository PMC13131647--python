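"""Relative phosphopeptide abundance from search-engine quant tables.

Label-free MS1 post-processing: for each phosphosite, the intensity of the
phosphopeptide is divided by the intensity of the identical peptide without
the phosphorylation (fixed modifications such as cysteine alkylation must
match).  Intensities are summed over charge states before division.  When
the unmodified peptide is undetectable (zero denominator) the ratio is
UNDEFINED rather than infinite — a flag, because those cases typically
accompany very high phosphopeptide abundance and deserve inspection, not a
number.

Confidence filters applied before quantification:
  * protein probability strictly above 0.95 (ProteinProphet-style score);
  * for modified peptides, site-localization probability at least 0.80
    (PTMProphet-style score).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

PROTEIN_PROB_MIN = 0.95      # strict: records must exceed this
LOCALIZATION_MIN = 0.80      # inclusive: modified records must reach this

GENERIC_COLUMNS = [
    "peptide",
    "protein_id",
    "site_label",
    "is_modified",
    "localization_prob",
    "intensity",
    "protein_prob",
]

#: FragPipe combined_modified_peptide.tsv-style column names -> generic names.
FRAGPIPE_COLUMNS = {
    "Peptide Sequence": "peptide",
    "Protein": "protein_id",
    "Assigned Modifications": "site_label",
    "Modified": "is_modified",
    "Localization": "localization_prob",
    "Intensity": "intensity",
    "Protein Probability": "protein_prob",
}


@dataclass(frozen=True)
class PhosphoQuantRecord:
    """One quantified peptide row.

    ``site_label`` is residue letter + 1-based protein position ("T294");
    multi-phospho peptides carry comma-joined labels ("S303,T305").
    ``localization_prob`` may be NaN for unmodified rows.
    """

    peptide: str
    protein_id: str
    site_label: str
    is_modified: bool
    localization_prob: float
    intensity: float
    protein_prob: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"negative intensity for {self.peptide}")
        for name in ("protein_prob",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1] for {self.peptide}")
        if not math.isnan(self.localization_prob) and not (
            0.0 <= self.localization_prob <= 1.0
        ):
            raise ValueError(f"localization_prob outside [0,1] for {self.peptide}")
        if self.is_modified and not self.site_label:
            raise ValueError(f"modified record without site_label: {self.peptide}")

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(s for s in self.site_label.split(",") if s) if self.site_label else ()


@dataclass(frozen=True)
class RelativeAbundance:
    """Site-level modified/unmodified MS1 intensity ratio."""

    site_label: str
    ratio: float | None          # None == UNDEFINED (unmodified undetectable)
    modified_intensity: float
    unmodified_intensity: float

    @property
    def is_defined(self) -> bool:
        return self.ratio is not None


def _parse_bool(v: str) -> bool:
    s = v.strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no", ""}:
        return False
    raise ValueError(f"cannot parse boolean {v!r}")


def read_quant_table(
    path: str | Path, dialect: str = "generic"
) -> list[PhosphoQuantRecord]:
    """Read a TSV quant table in the ``generic`` or ``fragpipe`` dialect.

    The generic dialect expects the field names of
    :class:`PhosphoQuantRecord` verbatim; the fragpipe dialect maps
    FragPipe-style column headers onto them.  Missing intensity cells are
    read as 0 with a per-file count logged; missing mandatory columns fail
    with their names.
    """
    if dialect == "generic":
        mapping = {c: c for c in GENERIC_COLUMNS}
    elif dialect == "fragpipe":
        mapping = FRAGPIPE_COLUMNS
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [src for src in mapping if src not in header]
        if missing:
            raise ValueError(
                f"{path}: missing mandatory columns {missing} "
                f"(dialect {dialect!r})"
            )
        records: list[PhosphoQuantRecord] = []
        n_missing_intensity = 0
        for row in reader:
            g = {dst: row[src] for src, dst in mapping.items()}
            if g["intensity"].strip() == "":
                n_missing_intensity += 1
                g["intensity"] = "0"
            loc = g["localization_prob"].strip()
            records.append(
                PhosphoQuantRecord(
                    peptide=g["peptide"].strip(),
                    protein_id=g["protein_id"].strip(),
                    site_label=g["site_label"].strip(),
                    is_modified=_parse_bool(g["is_modified"]),
                    localization_prob=float(loc) if loc else math.nan,
                    intensity=float(g["intensity"]),
                    protein_prob=float(g["protein_prob"]),
                )
            )
    if n_missing_intensity:
        logger.info(
            "%s: %d rows with missing intensity read as 0", path, n_missing_intensity
        )
    return records


def write_quant_table(
    records: Iterable[PhosphoQuantRecord], path: str | Path, dialect: str = "generic"
) -> None:
    if dialect == "generic":
        header = GENERIC_COLUMNS
        getcol = {c: c for c in GENERIC_COLUMNS}
    elif dialect == "fragpipe":
        header = list(FRAGPIPE_COLUMNS)
        getcol = {src: dst for src, dst in FRAGPIPE_COLUMNS.items()}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for r in records:
            row = []
            for col in header:
                v = getattr(r, getcol[col])
                if isinstance(v, bool):
                    v = "true" if v else "false"
                elif isinstance(v, float) and math.isnan(v):
                    v = ""
                row.append(v)
            writer.writerow(row)


def filter_records(
    records: Sequence[PhosphoQuantRecord],
    protein_prob_min: float = PROTEIN_PROB_MIN,
    localization_min: float = LOCALIZATION_MIN,
) -> list[PhosphoQuantRecord]:
    """Apply confidence filters, preserving order.

    Protein probability must be strictly above ``protein_prob_min``
    ("above 0.95": a record at exactly 0.95 is removed).  Modified records
    additionally need localization probability at least ``localization_min``
    ("at least 80% confident": exactly 0.80 is kept).  Removal counts per
    rule are logged.
    """
    kept: list[PhosphoQuantRecord] = []
    n_prot = n_loc = 0
    for r in records:
        if not r.protein_prob > protein_prob_min:
            n_prot += 1
            continue
        if r.is_modified and not (
            not math.isnan(r.localization_prob)
            and r.localization_prob >= localization_min
        ):
            n_loc += 1
            continue
        kept.append(r)
    if n_prot or n_loc:
        logger.info(
            "filtered %d records on protein_prob <= %.2f and %d on "
            "localization_prob < %.2f",
            n_prot,
            protein_prob_min,
            n_loc,
            localization_min,
        )
    return kept


def relative_abundance(
    records: Sequence[PhosphoQuantRecord],
    site_label: str,
    *,
    include_multisite: bool = False,
) -> RelativeAbundance:
    """Modified/unmodified intensity ratio for one site.

    Pairs each modified peptide carrying ``site_label`` with unmodified
    records of the identical peptide sequence (fixed modifications are part
    of the peptide string, so they match by construction); intensities are
    summed over charge states (rows) on each side before division.
    Peptides carrying additional phosphosites are excluded unless
    ``include_multisite`` is set.  Records should already be filtered.
    """
    modified = [
        r
        for r in records
        if r.is_modified
        and site_label in r.sites
        and (include_multisite or len(r.sites) == 1)
    ]
    if not modified:
        raise ValueError(f"no modified records for site {site_label!r}")
    peptides = {r.peptide for r in modified}
    unmodified = [r for r in records if not r.is_modified and r.peptide in peptides]
    mod_sum = float(sum(r.intensity for r in modified))
    unmod_sum = float(sum(r.intensity for r in unmodified))
    ratio = (mod_sum / unmod_sum) if unmod_sum > 0 else None
    return RelativeAbundance(site_label, ratio, mod_sum, unmod_sum)


def site_table(
    records: Sequence[PhosphoQuantRecord],
    protein_id: str | None = None,
    **kwargs,
) -> list[RelativeAbundance]:
    """Relative abundance for every single-phospho site seen in ``records``
    (optionally restricted to one protein), in first-appearance order."""
    if protein_id is not None:
        records = [r for r in records if r.protein_id == protein_id]
    sites: list[str] = []
    for r in records:
        if r.is_modified and len(r.sites) == 1 and r.sites[0] not in sites:
            sites.append(r.sites[0])
    return [relative_abundance(records, s, **kwargs) for s in sites]


def write_site_tsv(results: Iterable[RelativeAbundance], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site_label\tratio\tmodified_intensity\tunmodified_intensity\n")
        for r in results:
            ratio = "UNDEF" if r.ratio is None else f"{r.ratio:.6g}"
            fh.write(
                f"{r.site_label}\t{ratio}\t{r.modified_intensity:.6g}\t"
                f"{r.unmodified_intensity:.6g}\n"
            )


def records_equal(a: PhosphoQuantRecord, b: PhosphoQuantRecord) -> bool:
    """Field-wise equality treating NaN localization as equal to NaN."""
    fa, fb = a, b
    if math.isnan(a.localization_prob) and math.isnan(b.localization_prob):
        fa = replace(a, localization_prob=0.0)
        fb = replace(b, localization_prob=0.0)
    return fa == fb
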