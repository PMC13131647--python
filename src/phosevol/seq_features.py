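"""Per-species protein sequence features for the phosphosite/lifespan analysis.

The central primitive is the proline-directed phosphosite scan: a serine or
threonine immediately followed by proline ([ST]P) is counted as a predicted
phosphorylation site, the minimal recognition pattern of CMGC-family
kinases.  Around it sit the other per-species sequence features used in the
comparative regressions: site counts restricted to the C-terminal domain,
site density normalised to domain length, presence of a phosphoacceptor at a
reference-coordinate position (the T294-equivalent flag), net charge, and
charged/proline composition fractions.

All residue positions are 1-based throughout the package.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .alignment_map import ColumnMap

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")

#: Residues carrying +1/-1 unit charge under the simple convention used here
#: (K, R = +1; D, E = -1; histidine neutral; termini ignored).
POSITIVE = set("KR")
NEGATIVE = set("DE")


@dataclass(frozen=True)
class ProteinRecord:
    """One species' protein sequence.

    ``species_id`` is a whitespace-free token (typically Genus_species);
    ``sequence`` is an upper-case amino-acid string over the 20 standard
    letters plus X for unknown residues.
    """

    species_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.species_id or re.search(r"\s", self.species_id):
            raise ValueError(f"invalid species_id: {self.species_id!r}")
        if not self.sequence:
            raise ValueError(f"{self.species_id}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"{self.species_id}: non-amino-acid characters {sorted(bad)!r} "
                "(gap characters are not allowed in unaligned records)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureVector:
    """The per-species sequence features entering the lifespan regressions."""

    species_id: str
    n_sites_total: int
    n_sites_cterm: int
    cterm_start: int
    cterm_length: int
    site_density: float
    has_t294_equiv: bool | None
    net_charge: int
    frac_charged: float
    frac_proline: float

    #: Column order of the exported feature table.
    FIELDS = (
        "species_id",
        "n_sites_total",
        "n_sites_cterm",
        "cterm_start",
        "cterm_length",
        "site_density",
        "has_t294_equiv",
        "net_charge",
        "frac_charged",
        "frac_proline",
    )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file (plain or gzip).

    The header token before the first whitespace becomes the species id;
    sequences are upper-cased.  Duplicate ids, empty files and gap or other
    non-amino-acid characters are rejected with descriptive errors.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with opener(path, "rt") as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            sid = entry.id
            if sid in seen:
                raise ValueError(f"{path}: duplicate species_id {sid!r}")
            seen.add(sid)
            seq = str(entry.seq).upper()
            if "-" in seq or "." in seq:
                raise ValueError(
                    f"{path}: record {sid!r} contains gap characters; "
                    "supply unaligned sequences (use read_alignment for MSAs)"
                )
            records.append(ProteinRecord(sid, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def scan_phosphosites(sequence: str, *, allow_minus1_proline: bool = False) -> list[int]:
    """Return 1-based positions of predicted phosphosites in ``sequence``.

    A position i matches when sequence[i] is S or T and the residue at i+1
    is proline; a terminal S/T never matches.  With
    ``allow_minus1_proline=True`` a proline at i-1 also qualifies (the
    broader proline-directed pattern; off by default, since site counting
    uses the strict [ST]P motif).
    """
    out: list[int] = []
    for i in range(len(sequence)):
        if sequence[i] not in "ST":
            continue
        if i + 1 < len(sequence) and sequence[i + 1] == "P":
            out.append(i + 1)
        elif allow_minus1_proline and i > 0 and sequence[i - 1] == "P":
            out.append(i + 1)
    return out


def compute_features(
    record: ProteinRecord,
    cterm_start: int,
    *,
    composition_region: str = "cterm",
    allow_minus1_proline: bool = False,
) -> FeatureVector:
    """Compute the feature vector for one species.

    ``cterm_start`` is the 1-based index of the first C-terminal-domain
    residue in this species' own coordinates.  Site counts use the whole
    sequence (total) and the domain (cterm); charge and composition
    features are computed over the C-terminal domain by default
    (``composition_region="full"`` switches to the whole sequence).
    ``has_t294_equiv`` requires an alignment and is filled in separately
    (see :func:`has_phosphoacceptor_at_ref`); it is None here.

    A species whose C-terminal domain is empty (``cterm_start`` = length+1,
    produced by boundary projection for tails that are entirely gapped) gets
    ``cterm_length`` 0 and ``site_density`` NaN; such records are flagged
    for exclusion downstream.
    """
    n = len(record.sequence)
    if not 1 <= cterm_start <= n + 1:
        raise ValueError(
            f"{record.species_id}: cterm_start {cterm_start} outside 1..{n + 1}"
        )
    sites = scan_phosphosites(record.sequence, allow_minus1_proline=allow_minus1_proline)
    cterm_sites = [p for p in sites if p >= cterm_start]
    cterm_length = n - cterm_start + 1

    if composition_region == "cterm":
        region = record.sequence[cterm_start - 1 :]
    elif composition_region == "full":
        region = record.sequence
    else:
        raise ValueError(f"composition_region must be 'cterm' or 'full', got {composition_region!r}")

    pos = sum(1 for c in region if c in POSITIVE)
    neg = sum(1 for c in region if c in NEGATIVE)
    npro = region.count("P")
    rlen = len(region)
    return FeatureVector(
        species_id=record.species_id,
        n_sites_total=len(sites),
        n_sites_cterm=len(cterm_sites),
        cterm_start=cterm_start,
        cterm_length=cterm_length,
        site_density=(len(cterm_sites) / cterm_length) if cterm_length > 0 else float("nan"),
        has_t294_equiv=None,
        net_charge=pos - neg,
        frac_charged=((pos + neg) / rlen) if rlen else float("nan"),
        frac_proline=(npro / rlen) if rlen else float("nan"),
    )


def has_phosphoacceptor_at_ref(
    record: ProteinRecord,
    colmap: "ColumnMap",
    ref_position: int,
    *,
    accept_serine: bool = True,
) -> bool:
    """Does ``record`` carry a phosphoacceptor at a reference-coordinate site?

    The reference residue position (e.g. 294 in human coordinates) is mapped
    to its alignment column; the record's residue in that column is tested
    for S/T (or T only with ``accept_serine=False``).  A gap at the column
    returns False.  Serine is accepted by default because the counted motif
    is [ST]P, either acceptor.
    """
    col = colmap.res_to_col[ref_position]
    row = colmap.aligned_row(record.species_id)
    residue = row[col - 1]
    accepted = "ST" if accept_serine else "T"
    return residue in accepted


def features_table(
    records: Iterable[ProteinRecord],
    boundaries: dict[str, int],
    **kwargs,
) -> "pandas.DataFrame":  # noqa: F821 - forward name for doc purposes
    """Feature vectors for a collection, as a DataFrame in FIELDS order."""
    import pandas as pd

    rows = []
    for rec in records:
        fv = compute_features(rec, boundaries[rec.species_id], **kwargs)
        rows.append({f: getattr(fv, f) for f in FeatureVector.FIELDS})
    return pd.DataFrame(rows, columns=list(FeatureVector.FIELDS))


def write_features_tsv(df, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
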