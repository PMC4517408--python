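"""End-to-end orchestration: mine -> tree -> reconcile -> topotest -> modmap.

A single :class:`RunConfig` (YAML/JSON-loadable) drives the full chain on
real or simulated inputs. Every stage writes TSV/Newick outputs into the run
directory; stages are skipped on rerun when their inputs and configuration
are content-identical (hash manifest), and a provenance-stamped report ties
the numbers back to the stage files. All randomness flows from the single
config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .builder import ModuleAlignment, bootstrap_supports
from .mining import (
    SeedAlignment,
    build_profile,
    extract_modules,
    scan_proteins,
    write_fasta,
    write_hits_tsv,
)
from .modmap import detect_intragenic_duplications, links_table, map_orthologous_modules, render_synteny
from .reconcile import coalescence_depth, read_leaf_map, reconcile_unrooted
from .simulate import (
    SimulationParams,
    simulate_module_history,
    simulate_sequences,
    simulate_species_tree,
    write_dataset,
)
from .topotest import TopologyHypothesis, compare_hypotheses, regraft
from .trees import read_newick, to_newick, write_newick

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class RunConfig:
    proteomes: list[str] = field(default_factory=list)
    seed_alignment: str = ""
    species_tree: str = ""
    leaf_map: str = ""  # optional TSV; default split-at-pipe mapping
    outdir: str = "modevol_run"
    min_len: int = 100
    threshold_frac: float = 0.5
    support_threshold: int = 50
    bootstrap: int = 100
    criterion: str = "dc"
    seed: int = 0
    gene_tree: str = ""  # optional externally built Newick (skips mine/tree)
    regraft_clade: list[str] = field(default_factory=list)
    regraft_sister: list[str] = field(default_factory=list)
    depth_pair: list[str] = field(default_factory=list)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(data) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.species_tree:
            raise ConfigError("config must name a species tree")
        paths = [self.species_tree, *self.proteomes]
        if self.seed_alignment:
            paths.append(self.seed_alignment)
        if self.leaf_map:
            paths.append(self.leaf_map)
        if self.gene_tree:
            paths.append(self.gene_tree)
        for p in paths:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if not self.gene_tree and not (self.proteomes and self.seed_alignment):
            raise ConfigError("need either a gene tree or proteomes plus a seed alignment")
        if not (0 <= self.support_threshold <= 101):
            raise ConfigError("support_threshold must be within [0, 101]")
        if self.min_len < 1 or self.bootstrap < 1:
            raise ConfigError("min_len and bootstrap must be >= 1")


def _hash_content(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, (str, bytes)):
            h.update(p.encode() if isinstance(p, str) else p)
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
        h.update(b"\x00")
    return h.hexdigest()


def _file_bytes(path) -> bytes:
    return Path(path).read_bytes()


class _Stages:
    """Content-hash manifest for idempotent stage reruns."""

    def __init__(self, outdir: Path):
        self.path = outdir / ".stage_hashes.json"
        self.hashes = {}
        if self.path.exists():
            self.hashes = json.loads(self.path.read_text())

    def fresh(self, stage: str, digest: str, outputs: list[Path]) -> bool:
        return self.hashes.get(stage) == digest and all(p.exists() for p in outputs)

    def record(self, stage: str, digest: str) -> None:
        self.hashes[stage] = digest
        self.path.write_text(json.dumps(self.hashes, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also written as
    ``report.json`` in the run directory)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = _Stages(out)
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_hash": _hash_content(asdict(config)),
        },
        "stages": {},
    }

    species = read_newick(config.species_tree)

    # ---- mine -------------------------------------------------------------
    if config.gene_tree:
        gene_tree = read_newick(config.gene_tree)
        arch = None
        report["stages"]["mine"] = {"skipped": "external gene tree supplied"}
        report["stages"]["tree"] = {"imported": config.gene_tree}
    else:
        mine_out = [out / "hits.tsv", out / "modules.fasta", out / "architectures.tsv"]
        digest = _hash_content(
            *(_file_bytes(p) for p in config.proteomes),
            _file_bytes(config.seed_alignment),
            {"min_len": config.min_len, "threshold_frac": config.threshold_frac},
        )
        if not stages.fresh("mine", digest, mine_out):
            try:
                seed_aln = SeedAlignment.from_fasta(config.seed_alignment)
                profile = build_profile(seed_aln, threshold_frac=config.threshold_frac)
                proteins = []
                from .mining import _iter_proteins

                for p in config.proteomes:
                    proteins.extend(_iter_proteins(p))
                hits = scan_proteins(proteins, profile, min_len=config.min_len)
                records, arch = extract_modules(proteins, hits)
                write_hits_tsv(hits, mine_out[0])
                write_fasta(records, mine_out[1])
                arch.to_csv(mine_out[2], sep="\t", index=False)
                stages.record("mine", digest)
            except Exception as exc:
                raise StageError(f"stage 'mine' failed: {exc}") from exc
        arch = pd.read_csv(mine_out[2], sep="\t")
        n_hits = len(pd.read_csv(mine_out[0], sep="\t"))
        report["stages"]["mine"] = {
            "n_hits": n_hits,
            "n_genes": len(arch),
            "thresholds": {"min_len": config.min_len, "threshold_frac": config.threshold_frac},
        }

        # ---- tree ----------------------------------------------------------
        tree_out = [out / "module_tree.nwk"]
        digest = _hash_content(
            _file_bytes(mine_out[1]), {"bootstrap": config.bootstrap, "seed": config.seed}
        )
        if not stages.fresh("tree", digest, tree_out):
            try:
                aln = ModuleAlignment.from_fasta(mine_out[1])
                tree = bootstrap_supports(aln, replicates=config.bootstrap, seed=config.seed)
                write_newick(tree, tree_out[0])
                stages.record("tree", digest)
            except Exception as exc:
                raise StageError(f"stage 'tree' failed: {exc}") from exc
        gene_tree = read_newick(tree_out[0])
        report["stages"]["tree"] = {
            "n_leaves": len(gene_tree.leaf_names()),
            "bootstrap": config.bootstrap,
        }

    leaf_map = read_leaf_map(config.leaf_map) if config.leaf_map else None

    # ---- reconcile ---------------------------------------------------------
    try:
        rec = reconcile_unrooted(gene_tree, species, leaf_map, criterion=config.criterion)
        pd.DataFrame([rec.summary()]).to_csv(out / "reconciliation.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(
                ({"branch": k, "extra_lineages": v} for k, v in rec.extra_lineages.items()),
                key=lambda r: r["branch"],
            )
        ).to_csv(out / "extra_lineages.tsv", sep="\t", index=False)
        events = [
            {"node": ",".join(sorted(n.leaf_names())), "event": e}
            for n, e in rec.node_events.items()
        ]
        pd.DataFrame(sorted(events, key=lambda r: r["node"])).to_csv(
            out / "node_events.tsv", sep="\t", index=False
        )
    except Exception as exc:
        raise StageError(f"stage 'reconcile' failed: {exc}") from exc
    report["stages"]["reconcile"] = rec.summary() | {"criterion": config.criterion}

    # ---- coalescence depth -------------------------------------------------
    if config.depth_pair:
        sa, sb = config.depth_pair
        lm = leaf_map or {n: n.split("|")[0] for n in rec.gene_tree.leaf_names()}
        pairs = [
            (a, b)
            for a in rec.gene_tree.leaf_names()
            if lm[a] == sa
            for b in rec.gene_tree.leaf_names()
            if lm[b] == sb
        ]
        table, counts = coalescence_depth(pairs, rec.gene_tree, species, leaf_map, sa, sb)
        table.to_csv(out / "coalescence_depth.tsv", sep="\t", index=False)
        report["stages"]["coalescence_depth"] = counts

    # ---- topology test -----------------------------------------------------
    if config.regraft_clade and config.regraft_sister:
        try:
            alt = regraft(species, config.regraft_clade, config.regraft_sister)
            hyps = [
                TopologyHypothesis("original", species),
                TopologyHypothesis(
                    "regrafted",
                    alt,
                    f"{sorted(config.regraft_clade)} sister to {sorted(config.regraft_sister)}",
                ),
            ]
            cmp = compare_hypotheses(
                gene_tree,
                hyps,
                leaf_map,
                criterion=config.criterion,
                depth_pair=tuple(config.depth_pair) if config.depth_pair else None,
            )
            cmp.table.to_csv(out / "hypothesis_comparison.tsv", sep="\t", index=False)
            write_newick(alt, out / "species_tree_regrafted.nwk")
        except Exception as exc:
            raise StageError(f"stage 'topotest' failed: {exc}") from exc
        report["stages"]["topotest"] = {
            "table": cmp.table.to_dict(orient="records"),
            "verdicts": cmp.verdicts,
        }

    # ---- module map --------------------------------------------------------
    try:
        links = map_orthologous_modules(
            gene_tree, arch=arch, threshold=config.support_threshold,
            species_tree=species, leaf_map=leaf_map,
        )
        links_table(links).to_csv(out / "module_links.tsv", sep="\t", index=False)
        groups = detect_intragenic_duplications(gene_tree, threshold=config.support_threshold)
        pd.DataFrame(
            groups, columns=["gene", "n_modules", "modules", "module_indices", "support"]
        ).to_csv(out / "intragenic_groups.tsv", sep="\t", index=False)
        if arch is not None:
            (out / "synteny_map.txt").write_text(render_synteny(links, arch))
    except Exception as exc:
        raise StageError(f"stage 'modmap' failed: {exc}") from exc
    report["stages"]["modmap"] = {
        "n_links": len(links),
        "n_intragenic_groups": len(groups),
        "support_threshold": config.support_threshold,
    }

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


# ---------------------------------------------------------------------------
# Packaged fixture
# ---------------------------------------------------------------------------


def generate_fixture(seed: int, outdir) -> RunConfig:
    """Simulated 6-species, 3-family dataset plus a ready-to-run config.

    Small enough for the full pipeline to finish in well under two minutes;
    everything (species tree, proteomes with linker-separated modules, seed
    alignment, ground truth) is derived from ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species = simulate_species_tree(6, seed=seed, branch_scale=2.0, subs_scale=0.03)
    params = SimulationParams(
        n_init_modules=3,
        dup_rate=0.04,
        loss_rate=0.01,
        seed=seed,
        n_families=3,
        seq_length=150,
    )
    history = simulate_module_history(species, params)
    seqs = simulate_sequences(history, species, params)
    write_dataset(outdir, species, params, history, seqs)

    # proteomes: per species, concatenate each family's modules with linkers
    rng_lin = __import__("numpy").random.default_rng([seed % (2**31), 999])
    from .simulate import AMINO_ACIDS

    by_species: dict[str, list[tuple[str, str]]] = {sp: [] for sp in species.taxa}
    for gene in sorted(seqs):
        per_gene: dict[str, list[str]] = {}
        for name, seq in seqs[gene]:
            sp = name.split("|")[0]
            per_gene.setdefault(sp, []).append(seq)
        for sp, mods in per_gene.items():
            linker = "".join(
                AMINO_ACIDS[int(i)] for i in rng_lin.integers(20, size=25)
            )
            protein = linker + linker.join(mods) + linker
            by_species[sp].append((f"{sp}|{gene}", protein))
    for sp, recs in sorted(by_species.items()):
        write_fasta(recs, outdir / f"proteome_{sp}.fasta")

    # seed alignment: all true module sequences (equal length, ungapped)
    seed_records = []
    for gene in sorted(seqs):
        seed_records.extend(seqs[gene])
    write_fasta(seed_records, outdir / "seed_alignment.afa")

    taxa = species.taxa
    config = RunConfig(
        proteomes=[str(outdir / f"proteome_{sp}.fasta") for sp in sorted(taxa)],
        seed_alignment=str(outdir / "seed_alignment.afa"),
        species_tree=str(outdir / "species_tree.nwk"),
        outdir=str(outdir / "run"),
        seed=seed,
        min_len=100,
        threshold_frac=0.5,
        bootstrap=100,
        support_threshold=50,
        regraft_clade=[sorted(taxa)[-1]],
        regraft_sister=[sorted(taxa)[0]],
        depth_pair=sorted(taxa)[:2],
    )
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return config
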