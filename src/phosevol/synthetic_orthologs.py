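"""Synthetic stand-in SIRT6 orthologs (NOT real sequences).

Real SIRT6 orthologs must be fetched from NCBI (see
``scripts/fetch_real_data.py``).  This module builds small synthetic
stand-ins that reproduce the *layout* of the reported sites so the scan,
alignment-mapping and boundary-projection machinery can be exercised and
demonstrated offline:

* a conserved core, position 1-298 in human coordinates, identical across
  species, carrying the near-invariant S10-P site and the variable
  acceptor at position 294 (T in the long-lived human/bowhead stand-ins,
  A in guinea pig and mouse, followed by an invariant proline at 295);
* species-specific tails of differing lengths downstream of 298 carrying
  planted S/T-P dimers.

The human stand-in encodes seven C-terminal phospho positions (T294,
S303, T305, S326, S330, T337, S338) of which exactly six match the strict
[ST]P motif: T337 and S338 are adjacent, so only one of them can precede
a proline — T337 has proline at -1 and serine at +1 and therefore fails
the strict scan while matching the broader proline-directed pattern.
With the default domain boundary at residue 290, the stand-ins yield 6
(human), 2 (guinea pig), 6 (bowhead whale) strict C-terminal sites,
mirroring the counts reported for the real orthologs, and 1 for mouse.

Because the stand-ins are built to these counts, scanning them checks the
pipeline, not the biology.
"""

from __future__ import annotations

import numpy as np

from .alignment_map import Alignment
from .seq_features import ProteinRecord, scan_phosphosites

CORE_END = 298          # last conserved position, human coordinates
T294 = 294
DEFAULT_BOUNDARY = 290  # first C-terminal-domain residue (includes T294)

_FILLER = "ACDEFGHIKLMNQRVWY"  # no S/T/P: every motif below is planted

#: site -> acceptor letter planted in the human stand-in tail; True marks
#: strict [ST]P matches (proline at +1), False the -1-proline-only site.
HUMAN_TAIL_SITES = {
    303: ("S", True),
    305: ("T", True),
    326: ("S", True),
    330: ("S", True),
    337: ("T", False),   # P336-T337-S338: -1 proline only
    338: ("S", True),
}

_TAILS = {
    # species: (tail length beyond position 298, {position: acceptor}, has T294)
    "Homo_sapiens": (57, HUMAN_TAIL_SITES, True),
    "Balaena_mysticetus": (60, {305: ("T", True), 310: ("S", True),
                                320: ("S", True), 330: ("T", True),
                                340: ("S", True)}, True),
    "Cavia_porcellus": (50, {310: ("S", True), 330: ("T", True)}, False),
    "Mus_musculus": (48, {320: ("S", True)}, False),
}


def _core(rng: np.random.Generator) -> list[str]:
    core = list(rng.choice(list(_FILLER), size=CORE_END))
    core[9] = "S"       # S10
    core[10] = "P"
    core[T294] = "P"    # invariant +1 proline after the 294 acceptor
    return core


def build_orthologs() -> tuple[list[ProteinRecord], Alignment]:
    """Deterministically build the stand-in records and their alignment.

    The alignment is exact over the conserved core; the variable tails are
    left-justified and padded with trailing gaps (adequate here because no
    cross-species claim is made about tail columns).
    """
    rng = np.random.default_rng(2026)
    core = _core(rng)
    max_tail = max(t[0] for t in _TAILS.values())

    records: list[ProteinRecord] = []
    rows: list[tuple[str, str]] = []
    for species, (tail_len, sites, has_t294) in _TAILS.items():
        sp_core = core.copy()
        sp_core[T294 - 1] = "T" if has_t294 else "A"
        tail = list(rng.choice(list(_FILLER), size=tail_len))
        for pos, (letter, plus1_proline) in sites.items():
            i = pos - CORE_END - 1
            tail[i] = letter
            if plus1_proline:
                tail[i + 1] = "P"
            else:
                tail[i - 1] = "P"
        seq = "".join(sp_core) + "".join(tail)
        records.append(ProteinRecord(species, seq))
        rows.append((species, seq + "-" * (max_tail - tail_len)))

    _verify(records)
    return records, Alignment(rows)


def _verify(records: list[ProteinRecord]) -> None:
    """Internal consistency: planted layout is what the scan must find."""
    expected_cterm = {
        "Homo_sapiens": 6,
        "Balaena_mysticetus": 6,
        "Cavia_porcellus": 2,
        "Mus_musculus": 1,
    }
    for rec in records:
        sites = scan_phosphosites(rec.sequence)
        assert sites[0] == 10, "S10 site missing from stand-in core"
        n_cterm = sum(1 for p in sites if p >= DEFAULT_BOUNDARY)
        assert n_cterm == expected_cterm[rec.species_id], rec.species_id
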