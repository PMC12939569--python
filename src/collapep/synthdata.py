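"""Synthetic inputs with ground truth for every pipeline stage.

The generator emulates the shape of the study inputs without any downloads:

* collagen-like chains — an N-terminal signal peptide followed by a body
  dominated by Gly-X-Y triplets (X/Y drawn from a proline/alanine-rich
  collagen residue pool), with reference peptides planted at recorded,
  non-overlapping positions;
* annotation tables — toxicity / allergenicity / activity-vote / docking
  exports with exactly the requested numbers of failing and passing
  records, energies drawn around a reference ligand so the planted pass
  count survives the docking screen;
* gene networks — a preferential-attachment background with a small set of
  planted hub nodes wired to a large random neighbour set, edge confidences
  above the load threshold.

Every artifact draws from its own pseudo-random stream derived from the
master seed by a stable label, so adding a generator never perturbs the
others, and identical specs yield byte-identical files.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .digestion import EnzymeRule, cleavage_sites
from .seqmodel import ProteinChain

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
# Residue pool for the X/Y positions of collagen Gly-X-Y triplets:
# proline-rich with the charged/polar residues seen in collagen telopeptides.
_COLLAGEN_XY = "PPPAAASEKRQDGVLNT"
_SIGNAL_HYDROPHOBIC = "LLVVAAFFIWMC"


class SynthesisError(ValueError):
    """Raised when a spec cannot be realised (e.g. overcrowded plants)."""


@dataclass(frozen=True)
class SynthesisSpec:
    """Parameters of one synthetic data set. ``seed`` is mandatory."""

    seed: int
    n_chains: int = 2
    chain_length: int = 1000
    signal_length: int = 22
    gxy_fraction: float = 0.9
    planted_peptides: tuple[tuple[str, str, int], ...] = ()
    n_candidates: int = 107
    n_known: int = 0
    n_toxic: int = 1
    n_allergenic: int = 1
    n_high_activity: int = 27
    n_docking_pass: int = 4
    graph_nodes: int = 112
    graph_hubs: int = 4
    graph_attachment: int = 1

    def __post_init__(self) -> None:
        if self.gxy_fraction < 0 or self.gxy_fraction > 1:
            raise SynthesisError("gxy_fraction must be in [0, 1]")
        counts = (
            self.n_chains, self.chain_length, self.signal_length, self.n_candidates,
            self.n_known, self.n_toxic, self.n_allergenic, self.n_high_activity,
            self.n_docking_pass, self.graph_nodes, self.graph_hubs,
        )
        if any(c < 0 for c in counts):
            raise SynthesisError("counts must be non-negative")
        if self.graph_hubs >= self.graph_nodes:
            raise SynthesisError("graph_hubs must be below graph_nodes")


def _rng(spec: SynthesisSpec, label: str) -> np.random.Generator:
    return np.random.default_rng([spec.seed, zlib.crc32(label.encode())])


@dataclass
class GroundTruth:
    """What the generator planted, for exact downstream checks."""

    planted: dict[str, list[dict]] = field(default_factory=dict)
    signal_lengths: dict[str, int] = field(default_factory=dict)
    cascade_counts: dict[str, int] = field(default_factory=dict)
    known_candidates: list[str] = field(default_factory=list)
    toxic: list[str] = field(default_factory=list)
    allergenic: list[str] = field(default_factory=list)
    high_activity: list[str] = field(default_factory=list)
    docking_pass: list[str] = field(default_factory=list)
    hub_nodes: list[str] = field(default_factory=list)
    n_graph_nodes: int = 0
    n_graph_edges: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _gen_body(rng: np.random.Generator, length: int, gxy_fraction: float) -> list[str]:
    out: list[str] = []
    while len(out) < length:
        if rng.random() < gxy_fraction:
            out += ["G", _COLLAGEN_XY[rng.integers(len(_COLLAGEN_XY))],
                    _COLLAGEN_XY[rng.integers(len(_COLLAGEN_XY))]]
        else:
            out += [_RESIDUES[rng.integers(len(_RESIDUES))] for _ in range(3)]
    return out[:length]


def gen_chains(
    spec: SynthesisSpec,
    avoid_rules: Sequence[EnzymeRule] = (),
    max_attempts: int = 50,
) -> tuple[list[ProteinChain], GroundTruth]:
    """Collagen-like chains with planted reference peptides.

    Returns untrimmed chains (signal annotation set) and ground truth with
    planted coordinates in 1-based mature-chain coordinates. If
    ``avoid_rules`` are given, plant positions are redrawn until no rule
    cleaves inside a planted peptide (so digestion releases it intact or
    within a larger fragment, never split).
    """
    truth = GroundTruth()
    chains = []
    body_len = spec.chain_length - spec.signal_length
    if body_len <= 0:
        raise SynthesisError("chain_length must exceed signal_length")
    plant_total = sum(len(s) * c for s, _, c in spec.planted_peptides)
    if plant_total > body_len // 2:
        raise SynthesisError("planted peptides exceed half the mature chain; overcrowded")
    for ci in range(spec.n_chains):
        cid = f"SYN{ci + 1}"
        rng = _rng(spec, f"chain:{cid}")
        for attempt in range(max_attempts):
            signal = ["M"] + [
                _SIGNAL_HYDROPHOBIC[rng.integers(len(_SIGNAL_HYDROPHOBIC))]
                for _ in range(spec.signal_length - 1)
            ] if spec.signal_length else []
            body = _gen_body(rng, body_len, spec.gxy_fraction)
            # plant peptides at non-overlapping positions
            placements: list[tuple[int, str, str]] = []
            taken: set[int] = set()
            failed = False
            for pep, activity, count in spec.planted_peptides:
                for _ in range(count):
                    for _try in range(200):
                        start = int(rng.integers(0, body_len - len(pep) + 1))
                        span = range(start, start + len(pep))
                        if not taken.intersection(span):
                            taken.update(span)
                            placements.append((start, pep, activity))
                            break
                    else:
                        failed = True
                if failed:
                    break
            if failed:
                continue
            for start, pep, _ in placements:
                body[start : start + len(pep)] = list(pep)
            residues = "".join(signal) + "".join(body)
            chain = ProteinChain(
                id=cid,
                residues=residues,
                signal_end=spec.signal_length or None,
            )
            if avoid_rules:
                mature = ProteinChain(id=cid, residues="".join(body))
                sites = set()
                for r in avoid_rules:
                    sites.update(cleavage_sites(mature, r))
                # a site at bond b splits residues b and b+1 (0-based)
                bad = any(
                    any(start <= b < start + len(pep) - 1 for b in sites)
                    for start, pep, _ in placements
                )
                if bad:
                    continue
            chains.append(chain)
            truth.signal_lengths[cid] = spec.signal_length
            truth.planted[cid] = [
                {"sequence": pep, "activity": act, "start": start + 1, "end": start + len(pep)}
                for start, pep, act in sorted(placements)
            ]
            break
        else:
            raise SynthesisError(f"could not place planted peptides in {cid}; overcrowded")
    return chains, truth


def gen_candidates(spec: SynthesisSpec) -> list[str]:
    """Unique random peptide sequences (length 2-9) for cascade tests."""
    rng = _rng(spec, "candidates")
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < spec.n_candidates:
        length = int(rng.integers(2, 10))
        seq = "".join(_RESIDUES[rng.integers(len(_RESIDUES))] for _ in range(length))
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def gen_annotations(
    spec: SynthesisSpec,
    candidates: Sequence[str],
    reference_energy: tuple[float, float] = (90.0, 100.0),
) -> tuple[dict[str, list[dict]], GroundTruth]:
    """Annotation tables with planted pass/fail outcomes for the cascade.

    Plants, in order on a seeded shuffle of the candidates: ``n_known``
    already-catalogued sequences (emitted into the synthetic reference DB),
    then ``n_toxic`` and ``n_allergenic`` failures among the novel ones,
    ``n_high_activity`` positive classifier calls among the safe novel
    ones, and ``n_docking_pass`` docking passes among those. Ground-truth
    cascade counts follow by arithmetic.
    """
    rng = _rng(spec, "annotations")
    n = len(candidates)
    need = spec.n_known + spec.n_toxic + spec.n_allergenic
    if need > n or spec.n_high_activity > n - need or spec.n_docking_pass > spec.n_high_activity:
        raise SynthesisError("planted counts exceed available candidates")
    order = list(rng.permutation(n))
    known = [candidates[i] for i in order[: spec.n_known]]
    rest = order[spec.n_known :]
    toxic = [candidates[i] for i in rest[: spec.n_toxic]]
    allergenic = [candidates[i] for i in rest[spec.n_toxic : spec.n_toxic + spec.n_allergenic]]
    safe = rest[spec.n_toxic + spec.n_allergenic :]
    high = [candidates[i] for i in safe[: spec.n_high_activity]]
    docking_pass = set(high[: spec.n_docking_pass])

    ref_ce, ref_cie = reference_energy
    tables: dict[str, list[dict]] = {"toxicity": [], "allergenicity": [], "activity": [], "docking": []}
    clfs = ("lr", "svm", "mlp")
    for seq in candidates:
        tables["toxicity"].append({"sequence": seq, "label": "toxic" if seq in toxic else "non-toxic"})
        tables["allergenicity"].append(
            {"sequence": seq, "label": "allergenic" if seq in allergenic else "non-allergenic"}
        )
        votes = {c: "low_non" for c in clfs}
        if seq in high:
            for c in rng.choice(clfs, size=int(rng.integers(1, 4)), replace=False):
                votes[c] = "high"
        tables["activity"].append({"sequence": seq, **votes})
        if seq in docking_pass:
            ce = ref_ce + float(rng.uniform(1.0, 30.0))
            cie = ref_cie + float(rng.uniform(1.0, 30.0))
        else:
            # at least one energy strictly below the reference
            if rng.random() < 0.5:
                ce = ref_ce - float(rng.uniform(1.0, 30.0))
                cie = ref_cie + float(rng.uniform(-20.0, 20.0))
            else:
                ce = ref_ce + float(rng.uniform(-20.0, 20.0))
                cie = ref_cie - float(rng.uniform(1.0, 30.0))
        tables["docking"].append(
            {"sequence": seq, "cdocker_energy": f"{ce:.4f}", "cdocker_interaction": f"{cie:.4f}"}
        )

    truth = GroundTruth(
        known_candidates=known,
        toxic=toxic,
        allergenic=allergenic,
        high_activity=high,
        docking_pass=sorted(docking_pass),
        cascade_counts={
            "input": n,
            "novelty": n - spec.n_known,
            "safety": n - spec.n_known - spec.n_toxic - spec.n_allergenic,
            "activity": spec.n_high_activity,
            "docking": spec.n_docking_pass,
        },
    )
    return tables, truth


def gen_graph(spec: SynthesisSpec) -> tuple[nx.Graph, GroundTruth]:
    """Preferential-attachment background plus planted hub nodes.

    Hubs are wired to 30% of the background nodes (and chained to each
    other), so every centrality should place them at the top; the sparse
    (tree-like) background keeps the graph fragile under edge percolation,
    which is what lets the stochastic EPC score separate hubs from
    well-connected background nodes. Edge confidences are drawn in
    (0.905, 0.999), above the default 0.9 load threshold.
    """
    rng = _rng(spec, "graph")
    n_bg = spec.graph_nodes - spec.graph_hubs
    g = nx.barabasi_albert_graph(
        n_bg, min(spec.graph_attachment, max(1, n_bg - 1)), seed=int(rng.integers(2**31))
    )
    g = nx.relabel_nodes(g, {i: f"G{i:04d}" for i in g.nodes()})
    hubs = [f"HUB{i + 1}" for i in range(spec.graph_hubs)]
    background = sorted(g.nodes())
    for hub in hubs:
        n_links = max(1, int(0.3 * len(background)))
        targets = rng.choice(len(background), size=n_links, replace=False)
        for t in targets:
            g.add_edge(hub, background[t])
    for a, b in zip(hubs, hubs[1:]):
        g.add_edge(a, b)
    for e in g.edges():
        g.edges[e]["combined_score"] = round(float(rng.uniform(0.905, 0.999)), 4)
    truth = GroundTruth(
        hub_nodes=hubs,
        n_graph_nodes=g.number_of_nodes(),
        n_graph_edges=g.number_of_edges(),
    )
    return g, truth


def _merge(*truths: GroundTruth) -> GroundTruth:
    out = GroundTruth()
    for t in truths:
        for name in vars(out):
            val = getattr(t, name)
            if isinstance(val, dict):
                getattr(out, name).update(val)
            elif isinstance(val, list):
                getattr(out, name).extend(v for v in val if v not in getattr(out, name))
            elif val:
                setattr(out, name, val)
    return out


def write_dataset(spec: SynthesisSpec, outdir: str | Path) -> GroundTruth:
    """Emit the full synthetic data set to a directory.

    Files: chains.fa, signals.tsv, refdb.tsv, candidates.tsv,
    annotations/{toxicity,allergenicity,activity,docking}.tsv, graph.tsv,
    ground_truth.json. Every file validates against its consuming loader.
    """
    from .seqmodel import write_fasta

    outdir = Path(outdir)
    (outdir / "annotations").mkdir(parents=True, exist_ok=True)

    chains, chain_truth = gen_chains(spec)
    write_fasta(chains, outdir / "chains.fa")
    with open(outdir / "signals.tsv", "w") as fh:
        fh.write("chain_id\tsignal_end\n")
        for c in chains:
            if c.signal_end:
                fh.write(f"{c.id}\t{c.signal_end}\n")

    candidates = gen_candidates(spec)
    with open(outdir / "candidates.tsv", "w") as fh:
        fh.write("sequence\n")
        for seq in candidates:
            fh.write(seq + "\n")

    tables, ann_truth = gen_annotations(spec, candidates)
    for kind, rows in tables.items():
        with open(outdir / "annotations" / f"{kind}.tsv", "w") as fh:
            cols = list(rows[0].keys())
            fh.write("\t".join(cols) + "\n")
            for row in rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")

    # synthetic reference DB: planted chain peptides + planted known candidates
    refs: list[tuple[str, str]] = []
    for pep, activity, _ in spec.planted_peptides:
        refs.append((pep, activity))
    for seq in ann_truth.known_candidates:
        refs.append((seq, "ACE inhibitor"))
    if not refs:  # loader rejects an empty DB; keep a sentinel entry
        refs.append(("VY", "ACE inhibitor"))
    with open(outdir / "refdb.tsv", "w") as fh:
        fh.write("sequence\tactivity\tic50_um\tsource\n")
        for seq, activity in dict.fromkeys(refs):
            fh.write(f"{seq}\t{activity}\t\tsynthetic\n")

    graph, graph_truth = gen_graph(spec)
    with open(outdir / "graph.tsv", "w") as fh:
        fh.write("geneA\tgeneB\tcombined_score\n")
        for a, b, d in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{d['combined_score']}\n")

    truth = _merge(chain_truth, ann_truth, graph_truth)
    (outdir / "ground_truth.json").write_text(truth.to_json())
    return truth
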