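"""Self-contained synthetic benchmarks with planted architecture-function
associations.

The generator emits the three inputs the pipeline consumes — a domain-hit
table, an OBO ontology and a GAF annotation file — plus the planted ground
truth.  Each planted GO term is assigned an ordered domain motif; carrier
proteins embed that motif N-to-C with realistic residue coordinates
(domain spans of 50-150 aa), optional promiscuous noise domains, and
unannotated linkers that deliberately straddle the 30 aa GAP boundary
(29/30/31 aa) so the GAP-insertion rule is exercised.  A fraction of
proteins carry two motifs (multi-label), and a fraction carry none
(negatives).  Everything is deterministic given the seed.

The ontology is a shallow DAG: three namespace roots, a layer of branch
terms, and the planted terms underneath (some attached by ``part_of`` as
well as ``is_a``), so annotation propagation has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np

from .architectures import DomainArchitecture, count_domains
from .classify import DomainArchitectureGoClassifier
from .evaluate import ConfusionCounts, prf
from .ontology import OntologyGraph, ancestors

ROOTS = {
    "GO:0003674": "molecular_function",
    "GO:0008150": "biological_process",
    "GO:0005575": "cellular_component",
}

#: Linker lengths below/around the GAP threshold (drawn when no GAP region
#: is wanted); 29 and 30 sit deliberately on the non-inserting side.
_SHORT_LINKERS = (0, 5, 10, 15, 20, 25, 29, 30)

_EXP_CODES = ("IDA", "IMP", "IGI", "IPI", "IEP", "EXP")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Benchmark shape; the defaults are the study conditions used by the
    acceptance run (200 proteins, 60-domain alphabet, 20 planted terms)."""

    n_proteins: int = 200
    n_domains: int = 60
    n_terms: int = 20
    motif_len_range: tuple[int, int] = (2, 3)
    promiscuous_fraction: float = 0.1
    noise_insert_rate: float = 0.3
    gap_region_rate: float = 0.3
    negative_fraction: float = 0.15
    multilabel_rate: float = 0.25
    train_fraction: float = 0.7
    min_class_size: int = 3
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("promiscuous_fraction", "noise_insert_rate",
                     "gap_region_rate", "negative_fraction",
                     "multilabel_rate", "train_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.motif_len_range[0] < 1 or \
                self.motif_len_range[0] > self.motif_len_range[1]:
            raise ValueError("motif_len_range must be (min, max) with min >= 1")
        if self.n_terms < 1 or self.n_proteins < 1 or self.n_domains < 2:
            raise ValueError("need at least 1 term, 1 protein and 2 domains")
        if self.motif_len_range[1] > self.n_domains:
            raise ValueError("motif longer than the domain alphabet")


@dataclass(frozen=True)
class BenchmarkTruth:
    """Planted ground truth: per-protein term sets, per-term motifs, and the
    train/test protein split."""

    planted: Mapping[str, frozenset[str]]
    motifs: Mapping[str, tuple[str, ...]]
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


@dataclass(frozen=True)
class SyntheticBenchmark:
    hits_tsv: str
    obo_text: str
    gaf_text: str
    truth: BenchmarkTruth
    config: BenchmarkConfig = field(default_factory=BenchmarkConfig)

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "hits.tsv").write_text(self.hits_tsv)
        (outdir / "go.obo").write_text(self.obo_text)
        (outdir / "annotations.gaf").write_text(self.gaf_text)
        lines = ["#protein_id\tsplit\tplanted_terms"]
        for pid in sorted(self.truth.planted):
            split = "train" if pid in set(self.truth.train_ids) else "test"
            terms = ",".join(sorted(self.truth.planted[pid]))
            lines.append(f"{pid}\t{split}\t{terms}")
        (outdir / "truth.tsv").write_text("\n".join(lines) + "\n")


def _term_id(i: int) -> str:
    return f"GO:{1000000 + i:07d}"


def _branch_id(j: int) -> str:
    return f"GO:{9000000 + j:07d}"


def generate(config: BenchmarkConfig = BenchmarkConfig()) -> SyntheticBenchmark:
    """Generate a benchmark; byte-identical outputs for equal configs."""
    rng = np.random.default_rng(config.seed)
    accessions = [f"IPR{d:06d}" for d in range(1, config.n_domains + 1)]
    order = rng.permutation(config.n_domains)
    n_prom = int(np.ceil(config.promiscuous_fraction * config.n_domains))
    promiscuous = [accessions[i] for i in order[:n_prom]]
    motif_pool = [accessions[i] for i in order[n_prom:]]
    if not motif_pool:
        raise ValueError("promiscuous_fraction leaves no motif domains")

    # --- planted terms, branches and motifs -------------------------------
    terms = [_term_id(i) for i in range(1, config.n_terms + 1)]
    n_branches = max(1, config.n_terms // 5)
    branches = [_branch_id(j) for j in range(1, n_branches + 1)]
    lo, hi = config.motif_len_range
    motifs: dict[str, tuple[str, ...]] = {}
    cursor = 0
    for t in terms:
        k = int(rng.integers(lo, hi + 1))
        motif = tuple(motif_pool[(cursor + i) % len(motif_pool)] for i in range(k))
        cursor += k
        motifs[t] = motif

    obo_text = _render_obo(terms, branches, n_branches)

    # --- proteins ----------------------------------------------------------
    n_neg = int(round(config.negative_fraction * config.n_proteins))
    n_carriers = config.n_proteins - n_neg
    hit_rows: list[str] = []
    gaf_rows: list[str] = []
    planted: dict[str, frozenset[str]] = {}

    def linker() -> int:
        if rng.random() < config.gap_region_rate:
            return int(rng.integers(31, 81))
        return int(_SHORT_LINKERS[rng.integers(len(_SHORT_LINKERS))])

    for k in range(config.n_proteins):
        pid = f"SP{k + 1:05d}"
        if k < n_carriers:
            term_idx = {k % config.n_terms}
            if config.n_terms > 1 and rng.random() < config.multilabel_rate:
                second = (k % config.n_terms + 1
                          + int(rng.integers(config.n_terms - 1))) % config.n_terms
                term_idx.add(second)
            my_terms = sorted(terms[i] for i in sorted(term_idx))
            elements: list[str] = []
            for t in my_terms:
                elements.extend(motifs[t])
            if rng.random() < config.noise_insert_rate and promiscuous:
                pos = int(rng.integers(len(elements) + 1))
                noise = promiscuous[rng.integers(len(promiscuous))]
                elements.insert(pos, noise)
        else:
            my_terms = []
            n_el = int(rng.integers(1, 4))
            elements = []
            for _ in range(n_el):
                if promiscuous and rng.random() < 0.7:
                    elements.append(promiscuous[rng.integers(len(promiscuous))])
                else:
                    elements.append(accessions[rng.integers(config.n_domains)])

        pos = 1 + linker()
        spans: list[tuple[str, int, int]] = []
        for acc in elements:
            dlen = int(rng.integers(50, 151))
            spans.append((acc, pos, pos + dlen - 1))
            pos = pos + dlen + linker()
        length = spans[-1][2] + linker() if spans else 100
        for acc, s, e in spans:
            hit_rows.append(f"{pid}\t{length}\t{acc}\tdomain\t{s}\t{e}")
        if rng.random() < 0.05:
            # family-type distractor hit; excluded from DAs downstream
            acc = accessions[rng.integers(config.n_domains)]
            hit_rows.append(f"{pid}\t{length}\t{acc}\tfamily\t1\t{min(60, length)}")

        planted[pid] = frozenset(my_terms)
        for t in my_terms:
            code = _EXP_CODES[rng.integers(len(_EXP_CODES))]
            gaf_rows.append(_gaf_row(pid, t, code))
        # distractor annotations: electronic evidence, and an occasional NOT
        if rng.random() < 0.10:
            t = terms[rng.integers(config.n_terms)]
            gaf_rows.append(_gaf_row(pid, t, "IEA"))
        if rng.random() < 0.03:
            t = terms[rng.integers(config.n_terms)]
            gaf_rows.append(_gaf_row(pid, t, "IDA", qualifier="NOT|enables"))

    train_ids, test_ids = _split(planted, config, rng)
    truth = BenchmarkTruth(
        planted=planted, motifs=motifs,
        train_ids=tuple(train_ids), test_ids=tuple(test_ids),
    )
    hits_tsv = ("protein_id\tprotein_length\tinterpro_accession\tentry_type"
                "\tstart\tend\n" + "\n".join(hit_rows) + "\n")
    gaf_text = "!gaf-version: 2.1\n" + "\n".join(gaf_rows) + "\n"
    return SyntheticBenchmark(
        hits_tsv=hits_tsv, obo_text=obo_text, gaf_text=gaf_text,
        truth=truth, config=config,
    )


def _gaf_row(pid: str, term: str, code: str, qualifier: str = "enables") -> str:
    cols = [
        "UniProtKB", pid, pid, qualifier, term, "GO_REF:0000001", code, "",
        "F", f"synthetic protein {pid}", "", "protein", "taxon:32630",
        "20160307", "SynthGen", "", "",
    ]
    return "\t".join(cols)


def _render_obo(terms, branches, n_branches) -> str:
    blocks = ["format-version: 1.2\nontology: synthetic-go"]
    for rid, name in ROOTS.items():
        blocks.append(f"[Term]\nid: {rid}\nname: {name}\nnamespace: {name}")
    for j, b in enumerate(branches):
        blocks.append(
            f"[Term]\nid: {b}\nname: branch {j + 1}\n"
            f"namespace: molecular_function\n"
            f"is_a: GO:0003674 ! molecular_function"
        )
    for i, t in enumerate(terms):
        parent = branches[i % n_branches]
        lines = [
            "[Term]",
            f"id: {t}",
            f"name: planted function {i + 1}",
            "namespace: molecular_function",
            f"is_a: {parent} ! branch",
        ]
        if i == 0:
            lines.append("alt_id: GO:1111111")
        if i % 5 == 4 and n_branches > 1:
            other = branches[(i + 1) % n_branches]
            lines.append(f"relationship: part_of {other} ! branch")
        blocks.append("\n".join(lines))
    # an obsolete term, dropped by the OBO reader
    blocks.append(
        "[Term]\nid: GO:1999999\nname: withdrawn function\n"
        "namespace: molecular_function\nis_obsolete: true"
    )
    return "\n\n".join(blocks) + "\n"


def _split(planted, config, rng) -> tuple[list[str], list[str]]:
    """Per-protein train/test split, repaired so that every planted term
    keeps >= min_class_size training carriers and >= 1 test carrier."""
    pids = sorted(planted)
    in_train = {p: bool(rng.random() < config.train_fraction) for p in pids}
    carriers: dict[str, list[str]] = {}
    for p in pids:
        for t in planted[p]:
            carriers.setdefault(t, []).append(p)
    for _ in range(4):  # a few repair passes; multi-label moves can interact
        ok = True
        for t in sorted(carriers):
            cs = carriers[t]
            train_c = [p for p in cs if in_train[p]]
            test_c = [p for p in cs if not in_train[p]]
            while len(train_c) < config.min_class_size and test_c:
                p = test_c.pop(0)
                in_train[p] = True
                train_c.append(p)
                ok = False
            if not test_c and len(train_c) > config.min_class_size:
                p = train_c.pop()
                in_train[p] = False
                ok = False
        if ok:
            break
    train_ids = [p for p in pids if in_train[p]]
    test_ids = [p for p in pids if not in_train[p]]
    return train_ids, test_ids


@dataclass(frozen=True)
class RecoveryResult:
    precision: float
    recall: float
    fscore: float
    n_queries: int


def score_recovery(
    model: DomainArchitectureGoClassifier,
    truth: BenchmarkTruth,
    das: Mapping[str, DomainArchitecture],
    ontology: OntologyGraph,
    f_min: float = 0.7,
    max_domains: int = 8,
) -> RecoveryResult:
    """Micro-averaged precision/recall/F over the held-out split.

    Predictions are compared with the planted terms; a predicted non-root
    ancestor of a planted term counts as correct (it is implied by the
    planted annotation) rather than as a false positive, but recall is owed
    only for the planted terms themselves.  Queries with more real domains
    than ``max_domains`` are outside the method's stated scope and are
    excluded from both predictions and truth.
    """
    queries = [
        das[p] for p in truth.test_ids
        if p in das and count_domains(das[p]) <= max_domains
    ]
    predictions = model.predict_records(queries, f_min=f_min,
                                        max_domains=max_domains)
    pred_by_protein: dict[str, set[str]] = {}
    for p in predictions:
        pred_by_protein.setdefault(p.protein_id, set()).add(p.term_id)
    pooled = ConfusionCounts(0, 0, 0)
    for da in queries:
        planted = set(truth.planted[da.protein_id])
        closure = set(planted)
        for t in planted:
            closure |= ancestors(ontology, t)
        predicted = pred_by_protein.get(da.protein_id, set())
        pooled = pooled + ConfusionCounts(
            tp=len(predicted & closure),
            fp=len(predicted - closure),
            fn=len(planted - predicted),
        )
    m = prf(pooled)
    return RecoveryResult(
        precision=m.precision, recall=m.recall, fscore=m.fscore,
        n_queries=len(queries),
    )
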