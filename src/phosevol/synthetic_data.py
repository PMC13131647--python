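"""Synthetic data with the statistical structure the analysis assumes.

Every stage of the comparative pipeline can be exercised without external
downloads: a pure-birth (Yule) phylogeny, maximum lifespans evolving by
Brownian motion on the log10 scale, protein sequences whose C-terminal
[ST]P site count depends on lifespan with a tunable effect size, and MS
quant tables with multiplicative noise and missingness.

The generators are deliberately simple where realism does not matter for
the statistics being tested: sequences have an identical conserved core
across species (so the true alignment is trivial) and the variable tail is
drawn from an alphabet free of serine and threonine, so that the number of
planted S/T-P dimers is exactly the number of sites the motif scan can
find.  What the generators do and do not emulate is documented in
the package methods note.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .alignment_map import Alignment
from .seq_features import ProteinRecord
from .ms_quant import PhosphoQuantRecord, write_quant_table

#: Tail/filler alphabet: no S/T, so every [ST]P motif is a planted one
#: (prolines are allowed — the motif needs an acceptor before them — which
#: keeps the proline fraction from degenerating into the site count).
FILLER_ALPHABET = "ACDEFGHIKLMNPQRVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study conditions.

    Defaults are chosen to resemble the mammal panel the analysis targets:
    ~tens-to-hundreds of species, log10 lifespans spread over roughly
    0.3-2.3 (2 y to 200 y) around a root of ~16 y, and a site-count/
    lifespan slope of a few sites per log10-year (short-lived species with
    ~2 C-terminal sites, the longest-lived with ~6-8).
    """

    n_species: int = 128
    birth_rate: float = 1.0              # splits per lineage per unit time
    sigma2: float = 0.05                 # Brownian rate, log10-years^2 per unit branch
    root_lifespan_log10: float = 1.2     # ~16 years at the root
    site_effect: float = 3.4             # extra C-terminal sites per unit log10 lifespan
    baseline_sites: float = 0.5          # expected sites at log10 lifespan 0
    cterm_length: int = 200              # residues in the variable tail
    core_length: int = 100               # residues in the conserved core
    t294_logistic_slope: float = 4.0     # per unit log10 lifespan
    t294_logistic_intercept: float = -7.0
    ms_noise_cv: float = 0.2             # CV of multiplicative intensity noise
    ms_missing_rate: float = 0.05        # per-intensity dropout probability
    ms_low_conf_fraction: float = 0.0    # fraction of rows planted below filters
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        for name in (
            "birth_rate",
            "sigma2",
            "site_effect",
            "baseline_sites",
            "ms_noise_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("ms_missing_rate", "ms_low_conf_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.core_length < 10:
            raise ValueError("core_length must be >= 10")

    @property
    def analog_position(self) -> int:
        """1-based core position of the optional T294-analog acceptor."""
        return self.core_length - 5

    @property
    def cterm_boundary(self) -> int:
        """1-based position of the first tail residue (true domain start)."""
        return self.core_length + 1


@dataclass
class SequenceBundle:
    """Generated sequences plus the ground truth behind them."""

    records: list[ProteinRecord]
    alignment: Alignment
    boundaries: dict[str, int]
    planted_sites: dict[str, int]       # planted tail dimers per species
    has_analog: dict[str, bool]         # T294-analog presence per species
    analog_position: int
    cterm_boundary: int


def _species_labels(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"sp{i:0{width}d}" for i in range(1, n + 1)]


def simulate_tree(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``cfg.n_species`` leaves.

    Starting from two lineages at the root, waiting times between splits
    are exponential with rate birth_rate x (current lineage count); a final
    waiting period at the full lineage count sets the tip era, so the tree
    is ultrametric with expected depth sum_{k=2..n} 1/(birth_rate k).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, b = cfg.n_species, cfg.birth_rate
    if b <= 0:
        raise ValueError("birth_rate must be positive to simulate a tree")

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node

    # active leaves and their birth times
    birth: dict[dendropy.Node, float] = {}
    active: list[dendropy.Node] = []
    for _ in range(2):
        child = root.new_child()
        birth[child] = 0.0
        active.append(child)

    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (b * k))
        idx = int(rng.integers(k))
        node = active.pop(idx)
        node.edge.length = t - birth.pop(node)
        for _ in range(2):
            child = node.new_child()
            birth[child] = t
            active.append(child)
    t += rng.exponential(1.0 / (b * n))

    labels = _species_labels(n)
    # deterministic label order: left-to-right leaf order in the tree
    for node in active:
        node.edge.length = t - birth.pop(node)
    for label, leaf in zip(labels, tree.leaf_node_iter()):
        leaf.taxon = tns.new_taxon(label)
    return tree


def simulate_lifespans(
    tree: dendropy.Tree,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Brownian log10 maximum lifespans on the tree.

    The root takes ``root_lifespan_log10``; every branch adds a zero-mean
    normal increment with variance sigma2 x branch length.  Returns a table
    with ``species_id``, ``log10_lifespan`` and the back-transformed
    ``max_lifespan_years``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    value: dict[dendropy.Node, float] = {}
    rows = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            value[node] = cfg.root_lifespan_log10
        else:
            bl = node.edge.length or 0.0
            value[node] = value[node.parent_node] + rng.normal(
                0.0, math.sqrt(cfg.sigma2 * bl)
            )
        if node.is_leaf():
            rows.append((node.taxon.label, value[node]))
    df = pd.DataFrame(rows, columns=["species_id", "log10_lifespan"])
    df["max_lifespan_years"] = 10.0 ** df["log10_lifespan"]
    return df


def _place_dimers(
    length: int, k: int, rng: np.random.Generator
) -> list[int]:
    """0-based start positions of k non-overlapping, non-adjacent dimers."""
    allowed = set(range(length - 1))
    starts: list[int] = []
    while len(starts) < k and allowed:
        s = int(rng.choice(sorted(allowed)))
        starts.append(s)
        allowed -= {s - 2, s - 1, s, s + 1, s + 2}
    return sorted(starts)


def simulate_sequences(
    tree: dendropy.Tree,
    lifespans: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SequenceBundle:
    """Sequences whose C-terminal site count depends on lifespan.

    Each species is a shared conserved core (no [ST]P except an optional
    T294-analog, whose presence probability is logistic in log10 lifespan)
    followed by a tail of ``cterm_length`` residues carrying
    K ~ Poisson(baseline_sites + site_effect x lifespan) planted S/T-P
    dimers; remaining tail positions are drawn from an S/T-free alphabet,
    so the motif scan recovers exactly the planted K.  The true alignment
    is the sequences themselves (equal lengths, no indels) and the true
    domain boundary is the first tail position.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    life = dict(zip(lifespans["species_id"], lifespans["log10_lifespan"]))
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [lb for lb in labels if lb not in life]
    if missing:
        raise ValueError(f"lifespans missing for leaves: {missing}")

    lam_max = max(
        cfg.baseline_sites + cfg.site_effect * life[lb] for lb in labels
    )
    if lam_max > cfg.cterm_length / 2:
        raise ValueError(
            f"expected site count {lam_max:.1f} exceeds tail capacity "
            f"{cfg.cterm_length / 2:.0f}; increase cterm_length or lower the effect"
        )

    filler = np.array(list(FILLER_ALPHABET))
    core = rng.choice(filler, size=cfg.core_length)
    apos = cfg.analog_position - 1            # 0-based
    core[apos + 1] = "P"                      # fixed +1 proline at the analog site

    records: list[ProteinRecord] = []
    planted: dict[str, int] = {}
    has_analog: dict[str, bool] = {}
    max_k = (cfg.cterm_length - 1) // 3 + 1
    for label in labels:
        ls = life[label]
        p_analog = 1.0 / (
            1.0 + math.exp(-(cfg.t294_logistic_intercept + cfg.t294_logistic_slope * ls))
        )
        analog = bool(rng.random() < p_analog)
        sp_core = core.copy()
        sp_core[apos] = "T" if analog else "A"

        lam = max(0.0, cfg.baseline_sites + cfg.site_effect * ls)
        k = min(int(rng.poisson(lam)), max_k)
        tail = rng.choice(filler, size=cfg.cterm_length)
        for s in _place_dimers(cfg.cterm_length, k, rng):
            tail[s] = "S" if rng.random() < 0.5 else "T"
            tail[s + 1] = "P"
        seq = "".join(sp_core) + "".join(tail)
        records.append(ProteinRecord(label, seq))
        planted[label] = k
        has_analog[label] = analog

    alignment = Alignment([(r.species_id, r.sequence) for r in records])
    boundaries = {r.species_id: cfg.cterm_boundary for r in records}
    return SequenceBundle(
        records=records,
        alignment=alignment,
        boundaries=boundaries,
        planted_sites=planted,
        has_analog=has_analog,
        analog_position=cfg.analog_position,
        cterm_boundary=cfg.cterm_boundary,
    )


def _noise_factor(cv: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative log-normal noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    s2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=size)


def simulate_ms_records(
    true_ratios: dict[str, float],
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    protein_id: str = "SIRT6_SYN",
    base_intensity: float = 1e8,
) -> tuple[list[PhosphoQuantRecord], dict[str, str]]:
    """Quant records for sites with known true modified/unmodified ratios.

    Per site: the unmodified intensity is log-normal around
    ``base_intensity``; the modified intensity is true ratio x unmodified x
    multiplicative noise (CV = ``ms_noise_cv``); each intensity is
    independently zeroed with probability ``ms_missing_rate``.  A fraction
    ``ms_low_conf_fraction`` of rows is planted below the confidence
    thresholds to exercise the filters.  Returns the records and the
    site -> peptide map.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    records: list[PhosphoQuantRecord] = []
    peptides: dict[str, str] = {}
    filler = np.array(list(FILLER_ALPHABET))
    for site, ratio in true_ratios.items():
        if ratio < 0:
            raise ValueError(f"true ratio for {site} must be nonnegative")
        pep = site[0] + "".join(rng.choice(filler, size=9)) + "K"
        peptides[site] = pep
        unmod = float(base_intensity * _noise_factor(0.5, 1, rng)[0])
        mod = float(ratio * unmod * _noise_factor(cfg.ms_noise_cv, 1, rng)[0])
        if rng.random() < cfg.ms_missing_rate:
            unmod = 0.0
        if rng.random() < cfg.ms_missing_rate:
            mod = 0.0
        low_conf = rng.random(2) < cfg.ms_low_conf_fraction
        records.append(
            PhosphoQuantRecord(
                peptide=pep,
                protein_id=protein_id,
                site_label="",
                is_modified=False,
                localization_prob=math.nan,
                intensity=unmod,
                protein_prob=0.90 if low_conf[0] else 0.99,
            )
        )
        records.append(
            PhosphoQuantRecord(
                peptide=pep,
                protein_id=protein_id,
                site_label=site,
                is_modified=True,
                localization_prob=0.50 if low_conf[1] else 0.95,
                intensity=mod,
                protein_prob=0.99,
            )
        )
    return records, peptides


def simulate_ms_table(
    true_ratios: dict[str, float],
    cfg: SimulationConfig,
    path: str | Path,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> list[PhosphoQuantRecord]:
    """Write a generic-dialect quant table for the given true ratios."""
    records, _ = simulate_ms_records(true_ratios, cfg, rng=rng, **kwargs)
    write_quant_table(records, path, dialect="generic")
    return records


def simulate_bundle(cfg: SimulationConfig, out_dir: str | Path) -> dict:
    """Generate and write a complete input bundle for the pipeline.

    Writes sequences (FASTA), the true alignment (aligned FASTA), the tree
    (Newick), a lifespan table (TSV), an MS quant table (TSV), and a JSON
    sidecar of ground-truth parameters.  Byte-identical under a fixed seed.
    Returns the ground-truth dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    tree = simulate_tree(cfg, rng)
    lifespans = simulate_lifespans(tree, cfg, rng)
    bundle = simulate_sequences(tree, lifespans, cfg, rng)

    with open(out / "sequences.fasta", "w") as fh:
        for r in bundle.records:
            fh.write(f">{r.species_id}\n{r.sequence}\n")
    with open(out / "alignment.fasta", "w") as fh:
        for sid, row in bundle.alignment.rows:
            fh.write(f">{sid}\n{row}\n")
    tree.write(path=str(out / "tree.nwk"), schema="newick", suppress_rooting=True)
    life_out = lifespans.copy()
    life_out["max_lifespan_years"] = life_out["max_lifespan_years"].map(
        lambda v: f"{v:.6g}"
    )
    life_out[["species_id", "max_lifespan_years"]].to_csv(
        out / "lifespans.tsv", sep="\t", index=False
    )
    true_ratios = {"T294": 1.12, "S303": 11.7, "S330": 1.53, "S338": 83.4}
    simulate_ms_table(true_ratios, cfg, out / "quant.tsv", rng=rng)

    truth = {
        "config": dataclasses.asdict(cfg),
        "analog_position": bundle.analog_position,
        "cterm_boundary": bundle.cterm_boundary,
        "planted_sites": bundle.planted_sites,
        "has_analog": bundle.has_analog,
        "ms_true_ratios": true_ratios,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
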