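"""End-to-end pipeline: reads + known pairs -> fusion and f-circRNA tables.

Stages, mirroring the five-step workflow:

1. optional decoy filtering — reads aligning contiguously to a supplied
   transcriptome FASTA are dropped (skipped with a notice when no
   transcriptome is given; correctness is unchanged, only more compute);
2. bipartite partition of the known fusion partner genes into sets U and V;
3. low-penalty re-alignment of reads against the partner genes (k-mer
   seeded, exact DP) and paired-chiastic-clipping signal detection between
   known partners;
4. majority-vote breakpoint inference, fusion reconstruction, support
   recalibration and the Wilcoxon junction-balance annotation;
5. back-splice detection on each reconstructed fusion: chiastic split,
   rotation transform, re-verification, junction clustering into
   f-circRNA calls.

All iteration orders are fixed, so identical inputs reproduce identical
output tables byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from circfuse.align_core import (
    DEFAULT_SCORING,
    ReadAlignment,
    ScoringParams,
    local_align,
    select_partial_hits,
    select_unaligned,
    trim_terminal_gap_blocks,
)
from circfuse.fcirc_call import (
    FcircCall,
    call_fcirc,
    canonicalize_junction,
    detect_chiastic,
    transform_backspliced,
    verify_backsplice,
)
from circfuse.fusion_call import (
    FusionCall,
    balance_test,
    canonicalize_breakpoint,
    detect_pcc,
    filter_calls,
    infer_breakpoints,
    reconstruct_fusion,
    recalibrate,
)
from circfuse.fusion_graph import build_bipartition, known_partners, load_fusion_pairs
from circfuse.io_utils import (
    read_fasta,
    read_fastq,
    run_external_aligner,
    write_sam,
)
from circfuse.seedindex import KmerIndex, seed_window

logger = logging.getLogger(__name__)

FUSION_COLUMNS = ["gene5", "gene3", "bp5", "bp3", "junction_pos", "support",
                  "balance_p", "readthrough", "catalogue_orientation",
                  "fusion_seq"]
FCIRC_COLUMNS = ["gene5", "gene3", "circle_start", "circle_end", "support",
                 "spans_fusion"]


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run."""

    fastq1: str | Path
    fusions_tsv: str | Path
    genes_fasta: str | Path
    out_dir: str | Path
    fastq2: str | Path | None = None
    transcriptome: str | Path | None = None
    aligner_cmd: str | None = None
    min_clip: int = 8           # smallest soft clip worth explaining (PCC)
    pcc_slack: int = 3          # in-read boundary slack (micro-homology)
    min_overlap: int = 5        # junction overlap for a supporting read
    min_support: int = 3        # linear fusion reporting threshold
    min_circ_support: int = 1   # f-circRNA reporting threshold
    circ_anchor: int = 12       # smallest back-splice segment placed separately
    cluster_tol: int = 2        # junction/breakpoint clustering tolerance
    min_isoform_votes: int = 2  # split reads required for a secondary breakpoint
    balance_alpha: float | None = None
    readthrough_dist: int = 100_000
    seed_k: int = 14
    scoring: ScoringParams = field(default_factory=ScoringParams)
    require_span: bool = True
    write_sam_files: bool = True

    @property
    def layout(self) -> str:
        return "paired" if self.fastq2 else "single"

    def validate(self) -> None:
        for label, path in (("fastq1", self.fastq1),
                            ("fusions_tsv", self.fusions_tsv),
                            ("genes_fasta", self.genes_fasta),
                            ("fastq2", self.fastq2),
                            ("transcriptome", self.transcriptome)):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label}: {path} does not exist")
        for name in ("min_clip", "min_overlap", "min_circ_support",
                     "circ_anchor", "seed_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class PipelineResult(NamedTuple):
    fusion_calls: list[FusionCall]
    fcirc_calls: list[FcircCall]  # all, incl. non-spanning (flagged)
    fusion_table: Path
    fcirc_table: Path
    sam_files: list[Path]
    log_file: Path


class _Read(NamedTuple):
    key: str        # unique per record: "<template>/<mate>"
    template: str   # read pair (or single read) id
    mate: int | None
    seq: str
    qual: str


def _load_reads(config: PipelineConfig) -> list[_Read]:
    reads: list[_Read] = []
    for mate, path in ((1, config.fastq1), (2, config.fastq2)):
        if path is None:
            continue
        for rec in read_fastq(path):
            m = mate if config.fastq2 else None
            key = f"{rec.read_id}/{m}" if m else rec.read_id
            reads.append(_Read(key, rec.read_id, m, rec.seq, rec.qual))
    if not reads:
        raise ValueError(f"no reads found in {config.fastq1}")
    return reads


def _drop_transcriptome_hits(reads: list[_Read], config: PipelineConfig) -> list[_Read]:
    """Stage 1: drop reads that align contiguously to the decoy transcriptome.

    A read is considered transcriptome-derived when its best seeded
    alignment passes the minimum score with soft clips below ``min_clip``
    (a clipped read may still straddle a fusion junction and must go on).
    Both mates of a pair are kept if either survives.
    """
    txome = read_fasta(config.transcriptome)
    index = KmerIndex(txome, k=config.seed_k)
    hits = index.scan([r.seq for r in reads])
    mapped_templates: dict[str, int] = {}
    mapped_keys: set[str] = set()
    for i, targets in hits.items():
        read = reads[i]
        for (ref_name, strand), bounds in sorted(targets.items()):
            lo, hi = seed_window(bounds, config.seed_k, len(read.seq),
                                 len(txome[ref_name]))
            alns = local_align(read.seq, txome[ref_name][lo:hi], config.scoring,
                               strands=strand)
            if not alns:
                continue
            aln = alns[0]
            if aln.cigar.lead_clip < config.min_clip \
                    and aln.cigar.tail_clip < config.min_clip:
                mapped_keys.add(read.key)
                break
    for read in reads:
        mapped_templates[read.template] = mapped_templates.get(read.template, 0) \
            + (1 if read.key in mapped_keys else 0)
    n_mates = {}
    for read in reads:
        n_mates[read.template] = n_mates.get(read.template, 0) + 1
    kept = [r for r in reads
            if mapped_templates[r.template] < n_mates[r.template]]
    logger.info("stage 1: %d of %d reads dropped as transcriptome-aligned",
                len(reads) - len(kept), len(reads))
    return kept


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and write the output tables.

    Returns all calls (fusion calls after the support filter; f-circRNA
    calls including non-spanning flagged ones).  Exit is clean even with
    zero calls — empty tables are still written.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_file = out_dir / "run.log"
    handler = logging.FileHandler(log_file, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("circfuse")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out_dir, log_file)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out_dir: Path, log_file: Path) -> PipelineResult:
    logger.info("thresholds: %s", {
        k: getattr(config, k) for k in (
            "min_clip", "pcc_slack", "min_overlap", "min_support",
            "min_circ_support", "circ_anchor", "cluster_tol", "balance_alpha",
            "readthrough_dist", "seed_k")})
    logger.info("scoring: %s", config.scoring)

    reads = _load_reads(config)
    logger.info("loaded %d read records (%s)", len(reads), config.layout)

    if config.transcriptome is not None:
        if config.aligner_cmd:
            alns = run_external_aligner(
                config.aligner_cmd, config.transcriptome, config.fastq1,
                config.fastq2, set(read_fasta(config.transcriptome)), out_dir)
            keep = {(a.read_id, a.mate or 0)
                    for a in select_unaligned(alns, config.layout)}
            reads = [r for r in reads if (r.template, r.mate or 0) in keep]
            logger.info("stage 1 (external aligner): %d reads kept", len(reads))
        else:
            reads = _drop_transcriptome_hits(reads, config)
    else:
        logger.info("stage 1 skipped: no transcriptome reference supplied")

    pairs = load_fusion_pairs(config.fusions_tsv)
    index = build_bipartition(pairs)
    logger.info("stage 2: %d pairs, |U|=%d |V|=%d dual=%d", len(pairs),
                len(index.setU), len(index.setV), len(index.dual))
    gene_seqs = read_fasta(config.genes_fasta)
    missing = sorted(index.genes() - set(gene_seqs))
    if missing:
        logger.warning("no sequence for %d catalogued gene(s): %s",
                       len(missing), ", ".join(missing[:10]))
    genes = {g: gene_seqs[g] for g in sorted(index.genes() & set(gene_seqs))}

    # ---- stage 3: seeded re-alignment against the partner gene sets -------
    seed_index = KmerIndex(genes, k=config.seed_k)
    seed_hits = seed_index.scan([r.seq for r in reads])
    logger.info("stage 3: %d of %d reads seeded", len(seed_hits), len(reads))

    # per read key: {gene: [alignments]}
    read_alns: dict[str, dict[str, list[ReadAlignment]]] = {}
    by_key: dict[str, _Read] = {r.key: r for r in reads}
    for i in sorted(seed_hits):
        read = reads[i]
        per_gene: dict[str, list[ReadAlignment]] = {}
        aligned: set[tuple[str, str]] = set()
        for (gene, strand), bounds in sorted(seed_hits[i].items()):
            lo, hi = seed_window(bounds, config.seed_k, len(read.seq),
                                 len(genes[gene]))
            aligned.add((gene, strand))
            for aln in local_align(read.seq, genes[gene][lo:hi], config.scoring,
                                   read_id=read.key, ref_id=gene,
                                   mate=read.mate, qual=read.qual,
                                   strands=strand):
                aln.ref_start += lo
                aln = trim_terminal_gap_blocks(aln, ref=genes[gene])
                per_gene.setdefault(gene, []).append(aln)
        # A clipped, confidently placed segment may have its complement on a
        # partner gene too short to seed (< k); align those partners in full.
        augment: set[tuple[str, str]] = set()
        for gene, alns in per_gene.items():
            for aln in alns:
                if aln.score <= 0:
                    continue
                if aln.cigar.lead_clip < config.min_clip \
                        and aln.cigar.tail_clip < config.min_clip:
                    continue
                for partner in known_partners(index, gene):
                    if partner in genes and (partner, aln.strand) not in aligned:
                        augment.add((partner, aln.strand))
        for gene, strand in sorted(augment):
            for aln in local_align(read.seq, genes[gene], config.scoring,
                                   read_id=read.key, ref_id=gene,
                                   mate=read.mate, qual=read.qual,
                                   strands=strand):
                aln = trim_terminal_gap_blocks(aln, ref=genes[gene])
                per_gene.setdefault(gene, []).append(aln)
        if per_gene:
            read_alns[read.key] = per_gene

    side = {g: index.side(g) for g in genes}
    all_alns = [a for per_gene in read_alns.values()
                for alns in per_gene.values() for a in alns]
    mate_of = {r.key: r.template for r in reads}
    selection = select_partial_hits(
        [a for a in all_alns if side.get(a.ref_id) in ("U", "both")],
        [a for a in all_alns if side.get(a.ref_id) in ("V", "both")],
        layout=config.layout, min_clip=config.min_clip, mate_of=mate_of)
    logger.info("stage 3: %d PCC candidates, %d support-only reads",
                len(selection.pcc), len(selection.support))

    # ---- PCC signal detection between known partners -----------------------
    signals: dict[tuple[str, str], list] = {}
    pair_reads: dict[frozenset[str], set[str]] = {}  # gene pair -> templates
    catalogued = {(p.gene5, p.gene3) for p in pairs}
    for key in sorted(read_alns):
        per_gene = read_alns[key]
        for gene in per_gene:
            pset = known_partners(index, gene)
            for partner in pset:
                if partner in per_gene or partner in genes:
                    pair_reads.setdefault(frozenset((gene, partner)),
                                          set()).add(mate_of[key])
        if key not in selection.pcc:
            continue
        genes_hit = sorted(per_gene)
        for gi, gene_a in enumerate(genes_hit):
            for gene_b in genes_hit[gi + 1:]:
                if gene_b not in known_partners(index, gene_a):
                    continue
                for aln_a in per_gene[gene_a]:
                    for aln_b in per_gene[gene_b]:
                        sig = detect_pcc(aln_a, aln_b, min_clip=config.min_clip,
                                         slack=config.pcc_slack, refs=genes)
                        if sig is None:
                            continue
                        b5, b3 = canonicalize_breakpoint(
                            genes[sig.gene5], sig.bp5, genes[sig.gene3], sig.bp3)
                        sig = replace(sig, bp5=b5, bp3=b3)
                        signals.setdefault((sig.gene5, sig.gene3),
                                           []).append(sig)
    logger.info("stage 3: PCC signals for %d gene pair(s)", len(signals))

    # ---- stage 4: breakpoints, reconstruction, recalibration ---------------
    fusion_calls: list[FusionCall] = []
    call_context: list[dict] = []  # per call: fusion ref + alignments
    for pair_key in sorted(signals):
        gene5, gene3 = pair_key
        # Reads back-spliced across the fusion point of gene5--gene3 mimic a
        # fusion in the *opposite* orientation; when the catalogued
        # orientation is itself observed, such reversed signal groups belong
        # to the back-splice stage of the catalogued call, not to a linear
        # call of their own.
        reversed_key = (gene3, gene5)
        if pair_key not in catalogued and reversed_key in catalogued \
                and reversed_key in signals:
            logger.info("pair %s--%s: %d signal(s) in reversed orientation "
                        "attributed to the catalogued call", gene5, gene3,
                        len(signals[pair_key]))
            continue
        pair_sigs = signals[pair_key]
        candidates = infer_breakpoints(pair_sigs, cluster_tol=config.cluster_tol)
        member_templates = pair_reads.get(frozenset(pair_key), set())
        cand_reads = [(r.key, r.seq) for r in reads
                      if r.template in member_templates
                      and r.key in read_alns
                      and (set(read_alns[r.key]) & {gene5, gene3})]
        cand_keys = {k for k, _ in cand_reads}
        # mates of candidate reads may carry junction or back-splice evidence
        cand_templates = {mate_of[k] for k in cand_keys}
        for r in reads:
            if r.template in cand_templates and r.key not in cand_keys:
                cand_reads.append((r.key, r.seq))
                cand_keys.add(r.key)
        for rank, cand in enumerate(candidates):
            # A lone stray split read must not spawn its own near-identical
            # reconstruction: recalibrated support cannot discriminate
            # between reconstructions a few bases apart, so secondary
            # breakpoints need independent split-read evidence.
            if rank > 0 and cand.votes < config.min_isoform_votes:
                continue
            fusion_ref = reconstruct_fusion(genes[gene5], cand.bp5,
                                            genes[gene3], cand.bp3)
            recal = recalibrate(cand_reads, fusion_ref, config.scoring,
                                min_overlap=config.min_overlap,
                                template_of=mate_of, seed_k=config.seed_k)
            lefts = [f[0] for f in recal.fragments]
            rights = [f[1] for f in recal.fragments]
            call = FusionCall(
                gene5=gene5, gene3=gene3, bp5=cand.bp5, bp3=cand.bp3,
                fusion_seq=fusion_ref.seq, junction_pos=fusion_ref.junction_pos,
                support=recal.support,
                balance_p=balance_test(lefts, rights),
                catalogue_orientation=(gene5, gene3) in catalogued,
            )
            fusion_calls.append(call)
            call_context.append({"call": call, "ref": fusion_ref,
                                 "recal": recal})

    kept = filter_calls(fusion_calls, min_support=config.min_support,
                        balance_alpha=config.balance_alpha)
    kept_ids = {id(c) for c in kept}
    call_context = [ctx for ctx in call_context if id(ctx["call"]) in kept_ids]
    logger.info("stage 4: %d fusion call(s) after support filter (of %d)",
                len(kept), len(fusion_calls))

    # ---- stage 5: back-splice search on each reconstructed fusion ----------
    fcirc_calls: list[FcircCall] = []
    sam_files: list[Path] = []
    for ctx in call_context:
        call: FusionCall = ctx["call"]
        fusion_ref = ctx["ref"]
        recal = ctx["recal"]
        junctions: list[tuple[int, int]] = []
        seen: set[tuple[str, int, int]] = set()
        backsplice_keys: dict[str, tuple[int, int]] = {}
        for key in sorted(recal.alignments):
            aln = recal.alignments[key]
            lead, tail = aln.cigar.lead_clip, aln.cigar.tail_clip
            if max(lead, tail) < config.circ_anchor:
                continue
            oriented = aln.oriented_seq
            cand = detect_chiastic(oriented, fusion_ref.seq, config.scoring,
                                   min_clip=config.circ_anchor, read_id=key,
                                   main=aln)
            if cand is None:
                continue
            transformed = transform_backspliced(oriented, cand.split_offset)
            junction = verify_backsplice(transformed, fusion_ref.seq, cand,
                                         config.scoring)
            if junction is None:
                continue
            junction = canonicalize_junction(fusion_ref.seq, *junction)
            template = mate_of[key]
            dedupe = (template, junction[0], junction[1])
            if dedupe in seen:  # a pair counts once per junction
                continue
            seen.add(dedupe)
            junctions.append(junction)
            backsplice_keys[key] = junction
        calls = call_fcirc(junctions, fusion_ref.junction_pos,
                           min_circ_support=config.min_circ_support,
                           cluster_tol=config.cluster_tol,
                           require_span=config.require_span,
                           gene5=call.gene5, gene3=call.gene3,
                           fusion_len=len(fusion_ref.seq))
        if config.layout == "paired":
            _flag_mate_consistency(calls, backsplice_keys, recal.alignments,
                                   mate_of, config.cluster_tol)
        fcirc_calls.extend(calls)
        if config.write_sam_files:
            sam_path = out_dir / f"{call.gene5}_{call.gene3}_{call.junction_pos}.sam"
            ref_name = f"{call.gene5}--{call.gene3}"
            out_alns = []
            for key in sorted(recal.alignments):
                aln = recal.alignments[key]
                if key in recal.supporting_ids or key in backsplice_keys:
                    out_alns.append(ReadAlignment(
                        read_id=key, mate=aln.mate, ref_id=ref_name,
                        ref_start=aln.ref_start, strand=aln.strand,
                        status=aln.status, cigar=aln.cigar, score=aln.score,
                        seq=aln.seq, qual=by_key[key].qual))
            write_sam(sam_path, {ref_name: len(fusion_ref.seq)}, out_alns)
            sam_files.append(sam_path)

    logger.info("stage 5: %d f-circRNA call(s) (%d spanning the fusion point)",
                len(fcirc_calls), sum(c.spans_fusion for c in fcirc_calls))

    fusion_table = out_dir / "fusions.tsv"
    fcirc_table = out_dir / "fcirc.tsv"
    _write_fusion_table(fusion_table, kept)
    view = [c for c in fcirc_calls if c.spans_fusion or not config.require_span]
    _write_fcirc_table(fcirc_table, view)
    return PipelineResult(fusion_calls=kept, fcirc_calls=fcirc_calls,
                          fusion_table=fusion_table, fcirc_table=fcirc_table,
                          sam_files=sam_files, log_file=log_file)


def _flag_mate_consistency(calls: list[FcircCall],
                           backsplice_keys: dict[str, tuple[int, int]],
                           alignments: dict[str, ReadAlignment],
                           mate_of: dict[str, str], tol: int) -> None:
    """Check that mates of back-splice reads lie inside the called circle."""
    for fc in calls:
        lo, hi = fc.circle_start - tol, fc.circle_end + tol
        consistent: bool | None = None
        for key, junction in backsplice_keys.items():
            if abs(junction[0] - fc.circle_start) > tol \
                    or abs(junction[1] - fc.circle_end) > tol:
                continue
            template = mate_of[key]
            for other, aln in alignments.items():
                if other == key or mate_of.get(other) != template:
                    continue
                ok = aln.ref_start >= lo and aln.ref_end <= hi
                consistent = ok if consistent is None else (consistent and ok)
        fc.mate_consistent = consistent


def _write_fusion_table(path: Path, calls: list[FusionCall]) -> None:
    rows = [{
        "gene5": c.gene5, "gene3": c.gene3, "bp5": c.bp5, "bp3": c.bp3,
        "junction_pos": c.junction_pos, "support": c.support,
        "balance_p": c.balance_p,
        "readthrough": "NA" if c.readthrough is None else c.readthrough,
        "catalogue_orientation": c.catalogue_orientation,
        "fusion_seq": c.fusion_seq,
    } for c in sorted(calls, key=lambda c: (c.gene5, c.gene3, c.bp5, c.bp3))]
    pd.DataFrame(rows, columns=FUSION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.4f")


def _write_fcirc_table(path: Path, calls: list[FcircCall]) -> None:
    rows = [{
        "gene5": c.gene5, "gene3": c.gene3, "circle_start": c.circle_start,
        "circle_end": c.circle_end, "support": c.support,
        "spans_fusion": c.spans_fusion,
    } for c in sorted(calls, key=lambda c: (c.gene5, c.gene3,
                                            c.circle_start, c.circle_end))]
    pd.DataFrame(rows, columns=FCIRC_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.4f")
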