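"""End-to-end comparative analysis: sequences + alignment + tree + lifespans
-> per-species features -> OLS and PGLS per predictor, with a run manifest.

The stages are thin compositions of the library modules; everything the
run depends on (input hashes, the C-terminal boundary, the reference
species, thresholds, library versions, seed) is echoed into a
machine-readable manifest so that unstated choices are always explicit and
a run can be reproduced bit-for-bit from the manifest plus the inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment_map import (
    build_column_map,
    conservation_profile,
    project_cterm_boundary,
    read_alignment,
    write_boundaries_tsv,
    write_conservation_tsv,
)
from .ms_quant import filter_records, read_quant_table, site_table, write_site_tsv
from .phylo_pgls import brownian_vcv, fit_each_predictor, prune_and_match, read_newick
from .seq_features import (
    compute_features,
    FeatureVector,
    has_phosphoacceptor_at_ref,
    read_fasta,
)

logger = logging.getLogger(__name__)

DEFAULT_PREDICTORS = [
    "site_density",
    "has_t294_equiv",
    "net_charge",
    "frac_charged",
    "frac_proline",
]


@dataclass
class RunConfig:
    """Configuration of one comparative run (YAML-loadable)."""

    sequences: str
    alignment: str
    tree: str
    lifespans: str
    out_dir: str
    reference_id: str
    ref_boundary: int = 290          # first C-terminal-domain residue, reference coords
    t294_ref_position: int = 294     # reference coordinate of the acceptor site
    predictors: list[str] = field(default_factory=lambda: list(DEFAULT_PREDICTORS))
    log10_response: bool = True
    alignment_format: str = "fasta"
    quant_table: str | None = None
    quant_dialect: str = "generic"
    quant_protein: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_trait_table(
    records,
    alignment,
    reference_id: str,
    ref_boundary: int,
    lifespans: pd.DataFrame,
    t294_ref_position: int = 294,
    log10_response: bool = True,
) -> tuple[pd.DataFrame, list[float]]:
    """Feature + response table for the regressions, plus the conservation
    profile.  Species with an empty projected C-terminal domain are dropped
    (logged); lifespans must be positive before the log10 transform."""
    colmap = build_column_map(alignment, reference_id)
    boundaries = project_cterm_boundary(alignment, colmap, ref_boundary)
    profile = conservation_profile(alignment)

    rows = []
    for rec in records:
        if rec.species_id not in boundaries:
            logger.info("dropping %s: absent from alignment", rec.species_id)
            continue
        fv = compute_features(rec, boundaries[rec.species_id])
        if fv.cterm_length <= 0:
            logger.info(
                "dropping %s: empty C-terminal domain after projection",
                rec.species_id,
            )
            continue
        row = {f: getattr(fv, f) for f in FeatureVector.FIELDS}
        row["has_t294_equiv"] = has_phosphoacceptor_at_ref(
            rec, colmap, t294_ref_position
        )
        rows.append(row)
    feats = pd.DataFrame(rows, columns=list(FeatureVector.FIELDS))

    life = lifespans.copy()
    if "max_lifespan_years" not in life.columns:
        raise ValueError("lifespan table must have a max_lifespan_years column")
    if (life["max_lifespan_years"] <= 0).any():
        bad = life.loc[life["max_lifespan_years"] <= 0, "species_id"].tolist()
        raise ValueError(f"non-positive maximum lifespans for {bad}")
    if log10_response:
        life["log10_lifespan"] = np.log10(life["max_lifespan_years"])
        response = "log10_lifespan"
    else:
        response = "max_lifespan_years"
    traits = feats.merge(
        life[["species_id", response]], on="species_id", how="inner"
    )
    dropped = set(feats["species_id"]) - set(traits["species_id"])
    if dropped:
        logger.info("dropping %d species without lifespans: %s", len(dropped), sorted(dropped))
    return traits, profile


def run_comparative(cfg: RunConfig) -> dict:
    """Execute the full comparative analysis and write the results bundle.

    Returns a dict with the trait table, regression results and manifest.
    Any stage failure aborts with the stage name attached.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read inputs"
    try:
        records = read_fasta(cfg.sequences)
        alignment = read_alignment(cfg.alignment, cfg.alignment_format)
        tree = read_newick(cfg.tree)
        lifespans = pd.read_csv(cfg.lifespans, sep="\t")

        stage = "feature computation"
        traits, profile = build_trait_table(
            records,
            alignment,
            cfg.reference_id,
            cfg.ref_boundary,
            lifespans,
            t294_ref_position=cfg.t294_ref_position,
            log10_response=cfg.log10_response,
        )
        response = "log10_lifespan" if cfg.log10_response else "max_lifespan_years"

        stage = "tree/trait matching"
        pruned, matched = prune_and_match(tree, traits)

        stage = "regression"
        vcv = brownian_vcv(pruned, sorted(matched["species_id"]))
        results = fit_each_predictor(matched, cfg.predictors, vcv, response=response)

        stage = "ms quantification"
        ms_results = None
        if cfg.quant_table:
            quant = read_quant_table(cfg.quant_table, cfg.quant_dialect)
            ms_results = site_table(filter_records(quant), protein_id=cfg.quant_protein)
    except Exception as exc:
        raise RuntimeError(f"comparative run failed at stage '{stage}': {exc}") from exc

    stage = "write outputs"
    traits.to_csv(out / "features.tsv", sep="\t", index=False)
    results.to_csv(out / "regression.tsv", sep="\t", index=False)
    write_conservation_tsv(profile, out / "conservation.tsv")
    colmap = build_column_map(alignment, cfg.reference_id)
    write_boundaries_tsv(
        project_cterm_boundary(alignment, colmap, cfg.ref_boundary),
        out / "boundaries.tsv",
    )
    traits[["species_id", response, "site_density"]].to_csv(
        out / "scatter.tsv", sep="\t", index=False
    )
    if ms_results is not None:
        write_site_tsv(ms_results, out / "ms_sites.tsv")

    manifest = {
        "phosevol_version": __version__,
        "library_versions": _library_versions(),
        "config": dataclasses.asdict(cfg),
        "input_sha256": {
            key: _sha256(getattr(cfg, key))
            for key in ("sequences", "alignment", "tree", "lifespans")
        }
        | ({"quant_table": _sha256(cfg.quant_table)} if cfg.quant_table else {}),
        "n_species_analyzed": int(len(matched)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "traits": matched,
        "results": results,
        "conservation": profile,
        "ms_results": ms_results,
        "manifest": manifest,
    }


def _library_versions() -> dict[str, str]:
    import Bio
    import dendropy
    import scipy

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "biopython": Bio.__version__,
        "dendropy": dendropy.__version__,
    }


def scatter_plot(traits: pd.DataFrame, path: str | Path, response: str = "log10_lifespan"):
    """Diagnostic scatter of lifespan vs C-terminal site density."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(traits["site_density"], traits[response], s=12, alpha=0.7)
    ax.set_xlabel("C-terminal [ST]P site density")
    ax.set_ylabel(response)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
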