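"""End-to-end orchestration: discover -> classify -> catalog -> targets ->
expression, with a single resolved configuration and a rejection ledger."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import expression as expr_mod
from . import homology, hairpin_classify, precursor, synthetic_data, targets
from .catalog import MiRNARecord, assign_family, name_members, summarize
from .folding import EnergyParams, fold_mfe
from .seqio import (
    KnownMiRNA,
    Transcript,
    au_percent,
    write_catalog,
    write_fasta,
    write_gff3,
)

log = logging.getLogger("mirkit")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable threshold of the pipeline; defaults reproduce the
    published cut-offs."""

    max_mismatch: int = 2
    e_cut: float = 1e-2
    score_cut: float = 32.0
    flank_min: int = 20
    flank_max: int = 280
    flank_step: int = 20
    mfe_max: float = -15.0
    mfei_min: float = 0.5
    au_min_pct: float = 30.0
    au_max_pct: float = 70.0
    max_duplex_mismatch: int = 6
    family_mismatch: int = 4
    target_score_cut: float = 3.0
    max_gaps: int = 1
    reference_gene: str = "rRNA5S"
    calibrator_sample: str = "stem"
    name_prefix: str = "pde"
    max_interior: int = 30
    seed: int = 0

    def criteria(self) -> hairpin_classify.CriteriaConfig:
        return hairpin_classify.CriteriaConfig(
            mfe_max=self.mfe_max,
            mfei_min=self.mfei_min,
            au_min_pct=self.au_min_pct,
            au_max_pct=self.au_max_pct,
            max_duplex_mismatch=self.max_duplex_mismatch,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def dump_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class DiscoveryResult:
    records: list[MiRNARecord]
    accepted: list[hairpin_classify.PrecursorCandidate]
    rejections: pd.DataFrame
    summary: Optional[object]
    n_hits: int
    n_hits_filtered: int


def run_discovery(
    transcripts: Sequence[Transcript],
    reference: Sequence[KnownMiRNA],
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    params: EnergyParams | None = None,
) -> DiscoveryResult:
    """Homology hits -> candidate windows -> folding -> criteria -> catalog.

    Every accepted record is traceable through hit, window and structure;
    rejected hits are tallied with their failing-criterion reasons.
    """
    cfg = config or PipelineConfig()
    criteria = cfg.criteria()
    by_id = {t.id: t for t in transcripts}
    hits = homology.find_hits_many(transcripts, reference, cfg.max_mismatch)
    kept = homology.filter_hits(hits, cfg.e_cut, cfg.score_cut)
    log.info("homology: %d hits, %d after E/score filter", len(hits), len(kept))

    fold_cache: dict[str, object] = {}

    def fold(seq: str):
        if seq not in fold_cache:
            fold_cache[seq] = fold_mfe(seq, params, cfg.max_interior)
        return fold_cache[seq]

    best_by_locus: dict[tuple, hairpin_classify.PrecursorCandidate] = {}
    reject_rows: list[dict] = []
    for hit in kept:
        windows = precursor.extract_windows(
            by_id[hit.transcript_id],
            hit,
            cfg.flank_min,
            cfg.flank_max,
            cfg.flank_step,
        )
        candidates = [
            hairpin_classify.evaluate(w, fold(w.sequence), criteria) for w in windows
        ]
        best = hairpin_classify.select_best(candidates)
        locus = (hit.transcript_id, hit.strand, hit.start, hit.end)
        if best is None:
            reasons = sorted(
                {r for c in candidates for r in c.reasons}
            )
            reject_rows.append(
                {
                    "transcript_id": hit.transcript_id,
                    "mirna_id": hit.mirna_id,
                    "start": hit.start,
                    "end": hit.end,
                    "strand": hit.strand,
                    "reasons": ",".join(reasons) or "no-window",
                }
            )
            continue
        prev = best_by_locus.get(locus)
        if prev is None or best.mfei > prev.mfei:
            best_by_locus[locus] = best
    accepted = [best_by_locus[k] for k in sorted(best_by_locus)]
    records = []
    for cand in accepted:
        w = cand.window
        mature = w.mature
        records.append(
            MiRNARecord(
                name=mature,  # renamed below
                family=assign_family(mature, reference, cfg.family_mismatch),
                mature=mature,
                arm=cand.arm,
                au_pct=round(cand.au_pct, 1),
                mfe=round(cand.mfe, 2),
                mfei=round(cand.mfei, 2),
                precursor_id=w.transcript_id,
                locus_start=w.win_start,
            )
        )
    records = name_members(records, prefix=cfg.name_prefix)
    rejections = pd.DataFrame(
        reject_rows,
        columns=["transcript_id", "mirna_id", "start", "end", "strand", "reasons"],
    )
    summary = summarize(records) if records else None
    log.info(
        "discovery: %d loci accepted, %d hits rejected", len(accepted), len(reject_rows)
    )
    result = DiscoveryResult(
        records=records,
        accepted=accepted,
        rejections=rejections,
        summary=summary,
        n_hits=len(hits),
        n_hits_filtered=len(kept),
    )
    if outdir is not None:
        _write_discovery(result, by_id, cfg, Path(outdir))
    return result


def _write_discovery(
    result: DiscoveryResult,
    by_id: dict[str, Transcript],
    cfg: PipelineConfig,
    outdir: Path,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_catalog(result.records, outdir / "catalog.tsv")
    write_fasta(
        (
            (f"{rec.name}_precursor", cand.window.sequence)
            for rec, cand in zip(result.records, result.accepted)
        ),
        outdir / "precursors.fasta",
    )
    with open(outdir / "structures.txt", "w") as fh:
        for rec, cand in zip(result.records, result.accepted):
            fh.write(
                f">{rec.name}_precursor\n{cand.window.sequence}\n"
                f"{cand.structure.dotbracket} ({cand.structure.mfe:.2f})\n"
            )
    write_gff3(
        result.accepted,
        {tid: t.length for tid, t in by_id.items()},
        outdir / "loci.gff3",
    )
    result.rejections.to_csv(outdir / "rejections.tsv", sep="\t", index=False)
    if result.summary is not None:
        with open(outdir / "summary.json", "w") as fh:
            json.dump(dataclasses.asdict(result.summary), fh, indent=2)
    cfg.dump_yaml(outdir / "config_resolved.yaml")


def run_targets(
    records: Sequence[MiRNARecord],
    transcripts: Sequence[Transcript],
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> list[targets.TargetSite]:
    cfg = config or PipelineConfig()
    sites: list[targets.TargetSite] = []
    for rec in records:
        sites.extend(
            targets.scan_targets(
                rec.name,
                rec.mature,
                transcripts,
                cfg.target_score_cut,
                cfg.max_gaps,
            )
        )
    log.info("targets: %d sites at cut %.1f", len(sites), cfg.target_score_cut)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "mirna": s.mirna_id,
                "transcript_id": s.transcript_id,
                "site_start": s.site_start,
                "site_end": s.site_end,
                "score": s.score,
                "cleavage_pos": s.cleavage_pos,
            }
            for s in sites
        ).to_csv(outdir / "targets.tsv", sep="\t", index=False)
        with open(outdir / "alignments.txt", "w") as fh:
            for s in sites:
                fh.write(
                    f"# {s.mirna_id} -> {s.transcript_id}"
                    f" [{s.site_start},{s.site_end}) score={s.score}\n"
                    + targets.render_alignment(s)
                    + "\n\n"
                )
    return sites


def run_full(
    config: PipelineConfig | None = None,
    spec: synthetic_data.SimulationSpec | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """One command over a synthetic dataset: simulate, discover, scan
    targets and quantify expression. Returns a stage -> result mapping."""
    cfg = config or PipelineConfig()
    sim = spec or synthetic_data.default_spec(cfg.seed)
    transcripts, truth = synthetic_data.make_transcriptome(sim)
    reference = [
        KnownMiRNA(id=f"ref-miR{i + 1}", mature=p.mature, family=f"MIR{i + 1}")
        for i, p in enumerate(
            {p.mature: p for p in sim.planted}.values()
        )
    ]
    log.info("simulate: %d transcripts, %d truth rows", len(transcripts), len(truth))
    discovery = run_discovery(
        transcripts,
        reference,
        cfg,
        outdir=Path(outdir) / "discovery" if outdir else None,
    )
    tgt_transcripts, tgt_truth = synthetic_data.make_target_transcripts(
        sim.target_specs, sim.seed
    )
    sites = run_targets(
        discovery.records or [],
        tgt_transcripts,
        cfg,
        outdir=Path(outdir) / "targets" if outdir else None,
    )
    ct = synthetic_data.make_ct_table(
        sim.ct_specs,
        sim.seed,
        reference_gene=cfg.reference_gene,
        calibrator_sample=cfg.calibrator_sample,
    )
    measurements = [
        expr_mod.CtMeasurement(
            gene=r.gene, sample=r.sample, replicate=int(r.replicate), ct=float(r.ct)
        )
        for r in ct.itertuples()
    ]
    folds = expr_mod.relative_quant(
        measurements, cfg.reference_gene, cfg.calibrator_sample
    )
    log.info("expression: %d fold estimates", len(folds))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        tgt_truth.to_csv(outdir / "target_truth.tsv", sep="\t", index=False)
        ct.to_csv(outdir / "ct.tsv", sep="\t", index=False)
        expr_mod.write_expression(folds, outdir / "expression.tsv")
    return {
        "transcripts": transcripts,
        "truth": truth,
        "discovery": discovery,
        "target_truth": tgt_truth,
        "sites": sites,
        "expression": folds,
    }


def recovery_stats(result: DiscoveryResult, truth: pd.DataFrame) -> dict:
    """Planted-truth scorecard: planting recovery rate, accepted decoys and
    minus-strand recovery."""
    accepted_loci = [
        (
            c.window.transcript_id,
            c.window.strand,
            c.window.win_start,
            c.window.win_end,
        )
        for c in result.accepted
    ]

    def covered(row) -> bool:
        return any(
            tid == row.transcript_id
            and strand == row.strand
            and ws <= row.mature_start
            and we >= row.mature_end
            for tid, strand, ws, we in accepted_loci
        )

    plantings = truth[truth.kind == "planting"]
    decoys = truth[truth.kind == "decoy"]
    recovered = sum(covered(r) for r in plantings.itertuples())
    minus = plantings[plantings.strand == "-"]
    minus_recovered = sum(covered(r) for r in minus.itertuples())
    decoys_accepted = sum(
        any(
            tid == row.transcript_id
            and ws < row.element_end
            and we > row.element_start
            for tid, _, ws, we in accepted_loci
        )
        for row in decoys.itertuples()
    )
    return {
        "n_planted": len(plantings),
        "n_recovered": recovered,
        "recovery_rate": recovered / len(plantings) if len(plantings) else 1.0,
        "n_minus": len(minus),
        "n_minus_recovered": minus_recovered,
        "n_decoys": len(decoys),
        "n_decoys_accepted": decoys_accepted,
    }
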