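"""End-to-end driver: proteomes -> orthology -> families -> features ->
motifs -> presence matrix -> ancestral reconstruction -> gain report.

Each stage reads the previous stage's files from the run directory and
writes its own, together with a manifest of SHA-256 hashes keyed by a hash
of the configuration, so a rerun with an identical config and seed either
reuses or byte-identically reproduces every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import orthology as orth
from . import seqfeatures as sf
from .alphabet import global_frequencies
from .ancestral import Mk2AncestralModel
from .mcl import mcl_cluster
from .motifs import (MotifOccurrence, ZoopsMotifDiscovery, presence_matrix,
                     scan_sequences, write_meme_minimal)
from .simulate import EvolParams, MotifSpec, simulate_dataset, write_dataset
from .tree import Phylogeny

log = logging.getLogger("motiftrace")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "taxonomic_distribution", "STAGES"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a run needs.  Either ``simulate`` is set (synthetic run)
    or the four input paths are."""

    outdir: str = "run"
    seed: int = 0
    # inputs (real-data mode)
    proteomes_dir: str | None = None
    tree_path: str | None = None
    manifest_path: str | None = None
    core_boundaries_path: str | None = None
    # synthetic mode
    simulate: EvolParams | None = None
    # module parameters
    score_floor: float = 0.0
    inflation: float = 2.0
    focal_member: str | None = None        # "genome|protein"
    lps_p_max: float = 1e-15
    n_motifs: int = 30
    min_significance: float = 50.0
    scan_bits_fraction: float = 0.6
    root_prior: str = "stationary"
    tau: float = 0.92
    presence_cutoff: float = 0.5
    clade_labels: dict[str, str] = field(default_factory=dict)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = d["simulate"]
            sim["composition_profiles"] = [
                list(map(float, p)) for p in sim["composition_profiles"]]
            sim["repeat_tracks"] = [list(t) for t in sim["repeat_tracks"]]
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        if d.get("simulate") is not None:
            sim = d["simulate"]
            sim["composition_profiles"] = [np.array(p) for p in
                                           sim["composition_profiles"]]
            sim["repeat_tracks"] = [tuple(t) for t in sim["repeat_tracks"]]
            sim["motif_specs"] = [MotifSpec(**m) for m in sim["motif_specs"]]
            d["simulate"] = EvolParams(**sim)
        return cls(**d)


# ---------------------------------------------------------------------------
# small helpers

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(stage_dir: Path, cfg_hash: str) -> None:
    files = sorted(p for p in stage_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {"config_hash": cfg_hash,
                "files": {str(p.relative_to(stage_dir)): _sha256(p)
                          for p in files}}
    (stage_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))


def _stage_done(stage_dir: Path, cfg_hash: str) -> bool:
    mf = stage_dir / "manifest.json"
    if not mf.exists():
        return False
    try:
        m = json.loads(mf.read_text())
    except json.JSONDecodeError:
        return False
    return m.get("config_hash") == cfg_hash and all(
        (stage_dir / f).exists() for f in m.get("files", {}))


def _read_manifest_tsv(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["genome"], df["species"]))


def _read_core_tsv(path: Path) -> dict[tuple[str, str], int]:
    df = pd.read_csv(path, sep="\t", dtype={"core_end": int})
    return {(r.genome, r.protein): int(r.core_end)
            for r in df.itertuples(index=False)}


def _inputs(cfg: PipelineConfig, out: Path) -> dict[str, Path]:
    if cfg.simulate is not None:
        base = out / "sim"
    else:
        base = None
    return {
        "proteomes": Path(cfg.proteomes_dir) if cfg.proteomes_dir
        else base / "proteomes",
        "tree": Path(cfg.tree_path) if cfg.tree_path else base / "species.nwk",
        "manifest": Path(cfg.manifest_path) if cfg.manifest_path
        else base / "manifest.tsv",
        "cores": Path(cfg.core_boundaries_path) if cfg.core_boundaries_path
        else base / "core_boundaries.tsv",
    }


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: PipelineConfig) -> None:
    if cfg.simulate is None:
        raise PipelineError("simulate", "no simulator parameters configured")
    params = dataclasses.replace(cfg.simulate, seed=cfg.seed)
    tree, proteomes, bundle = simulate_dataset(params)
    write_dataset(Path(cfg.outdir) / "sim", tree, proteomes, bundle)


def stage_orthology(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    paths = _inputs(cfg, out)
    fastas = sorted(paths["proteomes"].glob("*.faa")) + \
        sorted(paths["proteomes"].glob("*.fasta"))
    if not fastas:
        raise PipelineError("orthology",
                            f"no FASTA files in {paths['proteomes']}")
    proteomes = {f.stem: orth.read_proteome_fasta(f, genome=f.stem)
                 for f in fastas}
    genomes = sorted(proteomes)
    aligner = orth.make_aligner()
    within = {g: orth.within_genome_scores(proteomes[g], aligner)
              for g in genomes}
    pairs = []
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1:]:
            scores = orth.score_table(proteomes[ga], proteomes[gb],
                                      aligner=aligner)
            hits_ab = orth.best_hits(proteomes[ga], proteomes[gb],
                                     cfg.score_floor, scores=scores)
            hits_ba = orth.best_hits(proteomes[gb], proteomes[ga],
                                     cfg.score_floor, scores=scores)
            pairs.extend(orth.classify_pairs(hits_ab, hits_ba, within[ga],
                                             within[gb], ga, gb,
                                             cross_scores=scores))
    sdir = out / "orthology"
    sdir.mkdir(parents=True, exist_ok=True)
    orth.write_pairs_tsv(pairs, sdir / "pairs.tsv")
    graph = orth.build_graph(pairs, "one_to_one")
    with open(sdir / "edges.tsv", "w") as fh:
        fh.write("a\tb\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{u[0]}|{u[1]}\t{v[0]}|{v[1]}\n")
        for node in sorted(n for n in graph.nodes if graph.degree(n) == 0):
            fh.write(f"{node[0]}|{node[1]}\t.\n")


def stage_cluster(cfg: PipelineConfig) -> None:
    import networkx as nx
    out = Path(cfg.outdir)
    edges = pd.read_csv(out / "orthology" / "edges.tsv", sep="\t", dtype=str)
    g = nx.Graph()
    for r in edges.itertuples(index=False):
        g.add_node(r.a)
        if r.b != ".":
            g.add_edge(r.a, r.b)
    if g.number_of_nodes() == 0:
        raise PipelineError("cluster", "orthology graph is empty")
    mapping, converged = mcl_cluster(g, inflation=cfg.inflation)
    if not converged:
        log.warning("MCL did not converge within max_iter")
    sdir = out / "cluster"
    sdir.mkdir(parents=True, exist_ok=True)
    rows = [(node, cid) for node, cid in sorted(mapping.items())]
    pd.DataFrame(rows, columns=["protein", "cluster"]).to_csv(
        sdir / "clusters.tsv", sep="\t", index=False)
    # family summary + focal family selection
    fam: dict[int, list[str]] = {}
    for node, cid in mapping.items():
        fam.setdefault(cid, []).append(node)
    summary = []
    for cid, members in sorted(fam.items()):
        genomes = {m.split("|")[0] for m in members}
        summary.append((cid, len(members), len(genomes)))
    pd.DataFrame(summary, columns=["cluster", "size", "genomes"]).to_csv(
        sdir / "families.tsv", sep="\t", index=False)
    if cfg.focal_member is not None:
        focal_cid = mapping.get(cfg.focal_member)
        if focal_cid is None:
            raise PipelineError("cluster",
                                f"focal member {cfg.focal_member!r} not in "
                                "the orthology graph")
    else:
        # widest species coverage; ties (e.g. ubiquitous housekeeping
        # families) broken by median protein length, then size
        paths = _inputs(cfg, out)
        lengths: dict[str, int] = {}
        for f in (sorted(paths["proteomes"].glob("*.faa"))
                  + sorted(paths["proteomes"].glob("*.fasta"))):
            for p in orth.read_proteome_fasta(f, genome=f.stem):
                lengths[f"{p.genome}|{p.protein}"] = len(p.sequence)

        def family_key(c: int):
            genomes = {m.split("|")[0] for m in fam[c]}
            med = float(np.median([lengths.get(m, 0) for m in fam[c]]))
            return (len(genomes), med, len(fam[c]), -c)

        focal_cid = max(fam, key=family_key)
    members = sorted(fam[focal_cid])
    with open(sdir / "focal.tsv", "w") as fh:
        fh.write("genome\tprotein\n")
        for m in members:
            g_, p_ = m.split("|", 1)
            fh.write(f"{g_}\t{p_}\n")


def _focal_sequences(cfg: PipelineConfig) -> list[tuple[str, str, str]]:
    """(genome, protein, noncatalytic sequence) for the focal family."""
    out = Path(cfg.outdir)
    paths = _inputs(cfg, out)
    focal = pd.read_csv(out / "cluster" / "focal.tsv", sep="\t", dtype=str)
    cores = _read_core_tsv(paths["cores"])
    rows = []
    for r in focal.itertuples(index=False):
        fasta = paths["proteomes"] / f"{r.genome}.faa"
        if not fasta.exists():
            fasta = paths["proteomes"] / f"{r.genome}.fasta"
        recs = {p.protein: p for p in
                orth.read_proteome_fasta(fasta, genome=r.genome)}
        seq = recs[r.protein].sequence
        core_end = cores.get((r.genome, r.protein), 0)
        rows.append((r.genome, r.protein,
                     sf.extract_noncatalytic(seq, core_end)))
    return rows


def stage_features(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    rows = _focal_sequences(cfg)
    background = global_frequencies([s for _, _, s in rows])
    feats: list[sf.Segment] = []
    for genome, protein, seq in rows:
        pid = f"{genome}|{protein}"
        feats.extend(sf.lps_scan(seq, background, p_max=cfg.lps_p_max,
                                 protein=pid))
        feats.extend(sf.find_tandem_repeats(seq, protein=pid))
        di = sf.disorder_index(seq)
        frac = float(np.mean(di < 0))
        feats.append(sf.Segment(pid, 1, len(seq), "disorder_heuristic",
                                round(frac, 6), "fraction_disordered"))
    sdir = out / "features"
    sdir.mkdir(parents=True, exist_ok=True)
    sf.write_features_tsv(feats, sdir / "features.tsv")
    summary = {}
    for genome, protein, seq in rows:
        pid = f"{genome}|{protein}"
        mine = [f for f in feats if f.protein == pid]
        summary[pid] = {
            "length": len(seq),
            "n_composition_bias": sum(f.kind == "composition_bias"
                                      for f in mine),
            "n_tandem_repeats": sum(f.kind == "tandem_repeat" for f in mine),
            "fraction_disordered_heuristic": next(
                (f.score for f in mine if f.kind == "disorder_heuristic"),
                None),
        }
    (sdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True))
    with open(sdir / "noncatalytic.faa", "w") as fh:
        for genome, protein, seq in rows:
            fh.write(f">{genome}|{protein}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def stage_motifs(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    paths = _inputs(cfg, out)
    recs = orth.read_proteome_fasta(out / "features" / "noncatalytic.faa")
    seqs = [r.sequence for r in recs]
    ids = [(r.genome, r.protein) for r in recs]
    est = ZoopsMotifDiscovery(n_motifs=cfg.n_motifs,
                              min_significance=cfg.min_significance,
                              seed=cfg.seed).fit(seqs)
    occurrences: list[MotifOccurrence] = []
    for motif in est.motifs_:
        occurrences.extend(scan_sequences(
            motif, seqs, min_bits=cfg.scan_bits_fraction * motif.max_score(),
            ids=ids))
    sdir = out / "motifs"
    sdir.mkdir(parents=True, exist_ok=True)
    write_meme_minimal(est.motifs_, sdir / "motifs.meme")
    with open(sdir / "occurrences.tsv", "w") as fh:
        fh.write("genome\tprotein\tmotif\tstart\tscore\n")
        for o in sorted(occurrences,
                        key=lambda o: (o.motif, o.genome, o.protein)):
            fh.write(f"{o.genome}\t{o.protein}\t{o.motif}\t{o.start}\t"
                     f"{o.score:.4f}\n")
    manifest = _read_manifest_tsv(paths["manifest"])
    mat = presence_matrix(occurrences, manifest,
                          motif_names=[m.name for m in est.motifs_])
    mat.to_csv(sdir / "presence.tsv", sep="\t", index_label="motif")
    meta = [(m.name, m.rank, m.width, m.consensus,
             round(m.significance(len(seqs)), 4), round(m.gamma, 6))
            for m in est.motifs_]
    pd.DataFrame(meta, columns=["motif", "rank", "width", "consensus",
                                "significance", "gamma"]).to_csv(
        sdir / "motif_summary.tsv", sep="\t", index=False)


def stage_ancestral(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    paths = _inputs(cfg, out)
    tree = Phylogeny.from_newick(paths["tree"].read_text())
    mat = pd.read_csv(out / "motifs" / "presence.tsv", sep="\t",
                      index_col="motif")
    missing = [c for c in mat.columns if c not in tree.leaf_labels]
    if missing:
        raise PipelineError("ancestral",
                            f"species not on the tree: {missing}")
    sdir = out / "ancestral"
    sdir.mkdir(parents=True, exist_ok=True)
    gains_rows = []
    marg_rows = []
    for motif in mat.index:
        states = {lab: int(mat.loc[motif].get(lab, 0))
                  for lab in tree.leaf_labels}
        model = Mk2AncestralModel(root_prior=cfg.root_prior,
                                  tau=cfg.tau).fit(tree, states, motif=motif)
        rep = model.report_
        gains_rows.append((
            motif, f"{rep.rates.a:.6g}", f"{rep.rates.b:.6g}",
            f"{rep.loglik:.6f}", rep.gain_count,
            ";".join(g[0] for g in rep.gain_events) or ".",
            ";".join(l[0] for l in rep.loss_events) or ".",
            f"{rep.scaled_likelihood:.4f}", rep.call,
            int(rep.boundary_fit)))
        for lab in tree.labels:
            m = model.marginals_[lab]
            marg_rows.append((motif, lab, f"{m[0]:.6f}", f"{m[1]:.6f}"))
    pd.DataFrame(gains_rows, columns=[
        "motif", "gain_rate", "loss_rate", "loglik", "gain_count",
        "gain_nodes", "loss_nodes", "scaled_likelihood", "call",
        "boundary_fit"]).to_csv(sdir / "gains.tsv", sep="\t", index=False)
    pd.DataFrame(marg_rows, columns=["motif", "node", "p_absent",
                                     "p_present"]).to_csv(
        sdir / "marginals.tsv", sep="\t", index=False)


def taxonomic_distribution(matrix: pd.DataFrame, tree: Phylogeny,
                           clade_labels: Mapping[str, str],
                           presence_cutoff: float = 0.5
                           ) -> dict[str, list[str]]:
    """Clades (node label -> clade name) where each motif's presence
    fraction among the clade's leaves reaches the cutoff, ordered by node
    depth (shallowest first), depth ties by clade name."""
    for node in clade_labels:
        tree.index_of(node)  # raises KeyError for unknown clades
    order = sorted(clade_labels,
                   key=lambda n: (tree.depth(tree.index_of(n)),
                                  clade_labels[n]))
    out: dict[str, list[str]] = {}
    for motif in matrix.index:
        present = {sp for sp in matrix.columns
                   if int(matrix.loc[motif, sp]) == 1}
        clades = []
        for node in order:
            leaves = tree.leaves_under(node)
            in_tree = [lf for lf in leaves if lf in matrix.columns]
            if not in_tree:
                continue
            frac = sum(lf in present for lf in in_tree) / len(in_tree)
            if frac >= presence_cutoff:
                clades.append(clade_labels[node])
        out[motif] = clades
    return out


def stage_report(cfg: PipelineConfig) -> None:
    out = Path(cfg.outdir)
    paths = _inputs(cfg, out)
    tree = Phylogeny.from_newick(paths["tree"].read_text())
    mat = pd.read_csv(out / "motifs" / "presence.tsv", sep="\t",
                      index_col="motif")
    gains = pd.read_csv(out / "ancestral" / "gains.tsv", sep="\t",
                        index_col="motif")
    summary = pd.read_csv(out / "motifs" / "motif_summary.tsv", sep="\t",
                          index_col="motif")
    labels = cfg.clade_labels or {
        lab: lab for i, lab in enumerate(tree.labels)
        if not tree.is_leaf[i]}
    dist = taxonomic_distribution(mat, tree, labels, cfg.presence_cutoff)
    rows = []
    for motif in summary.sort_values("rank").index:
        if motif not in mat.index:
            raise PipelineError("report", f"motif {motif!r} missing from "
                                "the presence matrix")
        g = gains.loc[motif]
        rows.append((int(summary.loc[motif, "rank"]), motif,
                     int(summary.loc[motif, "width"]),
                     summary.loc[motif, "consensus"],
                     ",".join(dist[motif]) or ".",
                     f"{float(g.scaled_likelihood):.4f}",
                     g.gain_nodes, g.call))
    sdir = out / "report"
    sdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["rank", "motif", "width", "consensus",
                                "taxonomic_distribution",
                                "scaled_likelihood_of_gain", "gain_nodes",
                                "call"]).to_csv(
        sdir / "report.tsv", sep="\t", index=False)


STAGES: dict[str, callable] = {
    "simulate": stage_simulate,
    "orthology": stage_orthology,
    "cluster": stage_cluster,
    "features": stage_features,
    "motifs": stage_motifs,
    "ancestral": stage_ancestral,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig, force: bool = False) -> pd.DataFrame:
    """Run all stages in order (skipping the simulator in real-data mode),
    reusing any stage whose checkpoint manifest matches the configuration.
    Returns the final report table."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(cfg.to_json())
    cfg_hash = cfg.config_hash()
    names = list(STAGES)
    if cfg.simulate is None:
        names.remove("simulate")
    dirty = force
    for name in names:
        stage_dir = out / ("sim" if name == "simulate" else name)
        if not dirty and _stage_done(stage_dir, cfg_hash):
            log.info("stage %s: checkpoint reused", name)
            continue
        dirty = True
        log.info("stage %s: running", name)
        try:
            STAGES[name](cfg)
        except PipelineError:
            raise
        except Exception as exc:
            partial = sorted(str(p.relative_to(out))
                             for p in stage_dir.rglob("*") if p.is_file()) \
                if stage_dir.exists() else []
            raise PipelineError(name, f"{exc} (partial outputs: {partial})"
                                ) from exc
        _write_manifest(stage_dir, cfg_hash)
    return pd.read_csv(out / "report" / "report.tsv", sep="\t")
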