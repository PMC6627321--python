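"""Pipeline driver: configuration, stage orchestration and report assembly.

Stage order mirrors the analysis workflow: sequences -> alignment
conservation -> codon census / uORFs -> composition -> structures ->
variants -> length statistics.  Every stage writes its own TSV/JSON as it
finishes (partial outputs are retained on failure) and contributes a section
to a combined JSON report that is byte-identical across reruns on identical
inputs (no timestamps inside the JSON; the run log carries them).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import composition, conservation, overlap_stats, structure, upstream_elements
from .seqio import read_alignment, read_annotations, read_fasta

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    fasta: str = ""
    annotations: str = ""
    alignment: str = ""
    alignment_format: str = "afa"
    structures: str = ""  # optional Vienna file
    variants: str = ""  # optional variant TSV
    output_dir: str = "utrscope_out"
    conservation: conservation.HotspotConfig = field(
        default_factory=conservation.HotspotConfig
    )
    orf: upstream_elements.OrfConfig = field(
        default_factory=upstream_elements.OrfConfig
    )
    composition: composition.SegmentationConfig = field(
        default_factory=composition.SegmentationConfig
    )
    gc_window: int = 50
    mw_sections: tuple[str, ...] = ("whole", "before", "after")
    verbosity: str = "info"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        try:
            if "conservation" in kwargs:
                kwargs["conservation"] = conservation.HotspotConfig(
                    **kwargs["conservation"]
                )
            if "orf" in kwargs:
                orf = dict(kwargs["orf"])
                if "start_codons" in orf:
                    orf["start_codons"] = tuple(orf["start_codons"])
                kwargs["orf"] = upstream_elements.OrfConfig(**orf)
            if "composition" in kwargs:
                comp = dict(kwargs["composition"])
                if "subsets" in comp:
                    comp["subsets"] = tuple(comp["subsets"])
                kwargs["composition"] = composition.SegmentationConfig(**comp)
            if "mw_sections" in kwargs:
                kwargs["mw_sections"] = tuple(kwargs["mw_sections"])
            cfg = cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.fasta:
            raise ConfigError("config: 'fasta' input is required")
        for name in ("fasta", "annotations", "alignment", "structures", "variants"):
            path = getattr(self, name)
            if path and not Path(path).exists():
                raise ConfigError(f"config: {name} file {path!r} does not exist")

    def defaults_yaml(self) -> str:
        out = dataclasses.asdict(self)
        return yaml.safe_dump(out, sort_keys=False)


def make_table1_like(records, uorfs_by_id: dict) -> pd.DataFrame:
    """One row per transcript mirroring the uORF comparison table; records
    without a uORF get empty uORF fields."""
    rows = []
    for rec in records:
        uorf = uorfs_by_id.get(rec.id)
        rows.append(
            {
                "id": rec.id,
                "species": rec.species,
                "start": uorf.start if uorf else None,
                "stop": uorf.stop_end if uorf else None,
                "len_nt": uorf.len_nt if uorf else None,
                "len_aa": uorf.len_aa if uorf else None,
                "peptide": uorf.peptide if uorf else "",
                "morf_start": rec.morf_start,
                "gap_to_morf": uorf.gap_to_morf if uorf else None,
                "overlaps_morf": uorf.overlaps_morf if uorf else None,
            }
        )
    return pd.DataFrame(rows)


def select_reported_uorf(rec, uorfs):
    """The reported uORF is the 5'-most one starting in the after-Intron-1
    section (where the conserved uATG sits, just past the splice junction);
    records without one fall back to the 5'-most uORF overall."""
    if not uorfs:
        return None
    sections = rec.sections()
    if "after" in sections:
        lo, hi = sections["after"]
        in_after = [u for u in uorfs if lo <= u.start <= hi]
        if in_after:
            return min(in_after, key=lambda u: u.start)
    return min(uorfs, key=lambda u: u.start)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages; returns the combined report dict.

    Writes per-stage TSV/JSON plus ``report.json`` and ``run.log`` under
    ``cfg.output_dir``.  A stage failure raises StageError naming the stage;
    outputs of completed stages remain on disk.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "parameters": {
            "conservation": dataclasses.asdict(cfg.conservation),
            "orf": dataclasses.asdict(cfg.orf),
            "composition": dataclasses.asdict(cfg.composition),
            "gc_window": cfg.gc_window,
        },
    }

    def stage(name):
        logger.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    # -- sequences ---------------------------------------------------------
    with stage("sequences"):
        records = read_fasta(cfg.fasta)
        if cfg.annotations:
            read_annotations(cfg.annotations, records)
        for rec in records:
            if rec.utr5_len is None:
                rec.utr5_len = len(rec.seq)
        by_id = {r.id: r for r in records}
        report["sequences"] = {
            "n_records": len(records),
            "ids": [r.id for r in records],
            "intronless": [r.id for r in records if not r.has_intron],
        }
        for rec in records:
            if not rec.has_intron:
                logger.warning("%s: intronless, sections = {whole}", rec.id)

    # -- conservation ------------------------------------------------------
    hotspots = None
    if cfg.alignment:
        with stage("conservation"):
            aln = read_alignment(cfg.alignment, cfg.alignment_format, by_id)
            profiles = conservation.profile_columns(aln)
            hotspots = conservation.call_hotspots(profiles, cfg.conservation, aln)
            run, run_len = conservation.longest_hotspot_run(hotspots)
            (outdir / "hotspots.json").write_text(
                conservation.hotspots_to_json(hotspots)
            )
            conservation.hotspots_to_bed(hotspots).to_csv(
                outdir / "hotspots.bed.tsv", sep="\t", index=False
            )
            report["conservation"] = {
                "n_hotspot_columns": len(hotspots),
                "n_runs": len(hotspots.runs),
                "longest_run": list(run) if run else None,
                "longest_run_len": run_len,
                "min_occupancy_count": conservation.min_occupancy_count(
                    aln.nrow, cfg.conservation.occupancy_min
                ),
            }

    # -- codon census ------------------------------------------------------
    with stage("codons"):
        census_rows = []
        for rec in records:
            census = upstream_elements.census_by_section(rec)
            for codon in census.codons:
                for section, positions in census.positions[codon].items():
                    census_rows.append(
                        {
                            "id": rec.id,
                            "codon": codon,
                            "section": section,
                            "count": len(positions),
                            "positions": ",".join(map(str, positions)),
                        }
                    )
        census_df = pd.DataFrame(census_rows)
        census_df.to_csv(outdir / "codon_census.tsv", sep="\t", index=False)
        report["codons"] = {
            "n_rows": len(census_df),
            "uatg_total": int(
                census_df.query("codon == 'ATG' and section == 'whole'")[
                    "count"
                ].sum()
            )
            if len(census_df)
            else 0,
        }

    # -- uORFs and contexts -------------------------------------------------
    with stage("uorf"):
        reported: dict = {}
        all_uorfs = []
        context_rows = []
        for rec in records:
            if rec.morf_start is None:
                logger.warning("%s: no morf_start, uORF stage skipped", rec.id)
                continue
            uorfs = upstream_elements.call_uorfs(rec, cfg.orf)
            all_uorfs.extend(uorfs)
            chosen = select_reported_uorf(rec, uorfs)
            if chosen:
                reported[rec.id] = chosen
            uctx = (
                upstream_elements.extract_context(rec, chosen.start)
                if chosen
                else None
            )
            mctx = upstream_elements.extract_context(rec, rec.morf_start)
            if uctx and len(uctx.window) < 21:
                logger.warning("%s: truncated uATG context", rec.id)
            context_rows.append(
                {
                    "id": rec.id,
                    "uorf_context": uctx.window if uctx else "",
                    "uorf_class": uctx.klass if uctx else "",
                    "morf_context": mctx.window,
                    "morf_class": mctx.klass,
                    "utga_minus9": upstream_elements.has_inframe_utga(rec),
                }
            )
        table1 = make_table1_like(records, reported)
        table1.to_csv(outdir / "uorfs.tsv", sep="\t", index=False)
        ctx_df = pd.DataFrame(context_rows)
        ctx_df.to_csv(outdir / "contexts.tsv", sep="\t", index=False)
        report["uorf"] = {
            "n_transcripts_with_uorf": len(reported),
            "n_uorfs_total": len(all_uorfs),
            "n_overlapping_morf": int(
                sum(1 for u in reported.values() if u.overlaps_morf)
            ),
            "context_classes": {
                "uorf": {
                    k: int(v)
                    for k, v in ctx_df["uorf_class"].value_counts().items()
                }
                if len(ctx_df)
                else {},
                "morf": {
                    k: int(v)
                    for k, v in ctx_df["morf_class"].value_counts().items()
                }
                if len(ctx_df)
                else {},
            },
        }

    # -- composition ---------------------------------------------------------
    with stage("composition"):
        gc_rows, seg_rows = [], []
        for rec in records:
            prof = composition.section_gc(rec)
            gc_rows.append(
                {
                    "id": rec.id,
                    "whole_pct": round(prof.whole_pct, 1),
                    "before_pct": round(prof.before_pct, 1)
                    if prof.before_pct is not None
                    else None,
                    "after_pct": round(prof.after_pct, 1)
                    if prof.after_pct is not None
                    else None,
                    "after_dominant": prof.after_dominant,
                    "before_dominant": prof.before_dominant,
                }
            )
            for seg in composition.segment_repetition_regions(
                rec.utr5_seq(), cfg.composition
            ):
                seg_rows.append(
                    {
                        "id": rec.id,
                        "label": seg.label,
                        "start": seg.start,
                        "end": seg.end,
                        "fraction": round(seg.fraction, 3),
                    }
                )
        pd.DataFrame(gc_rows).to_csv(outdir / "gc.tsv", sep="\t", index=False)
        pd.DataFrame(
            seg_rows, columns=["id", "label", "start", "end", "fraction"]
        ).to_csv(outdir / "segments.tsv", sep="\t", index=False)
        report["composition"] = {
            "n_after_dominant": sum(1 for r in gc_rows if r["after_dominant"]),
            "n_before_dominant": sum(1 for r in gc_rows if r["before_dominant"]),
            "n_segments": len(seg_rows),
        }

    # -- structures ----------------------------------------------------------
    if cfg.structures:
        with stage("structure"):
            loops_rows = []
            for db in structure.read_vienna(cfg.structures):
                loops = structure.enumerate_hairpins(db)
                rec = by_id.get(db.id)
                counts = structure.assign_sections(loops, rec) if rec else {}
                for loop in loops:
                    loops_rows.append(
                        {
                            "id": db.id,
                            "i": loop.i,
                            "j": loop.j,
                            "loop_len": loop.loop_len,
                            "section": loop.section,
                        }
                    )
                loops_rows.append(
                    {
                        "id": db.id,
                        "i": None,
                        "j": None,
                        "loop_len": len(loops),
                        "section": json.dumps(counts, sort_keys=True),
                    }
                )
            pd.DataFrame(loops_rows).to_csv(
                outdir / "hairpins.tsv", sep="\t", index=False
            )
            report["structure"] = {"n_rows": len(loops_rows)}

    # -- variants ------------------------------------------------------------
    if cfg.variants:
        with stage("variants"):
            if hotspots is None:
                raise ValueError(
                    "variant overlap needs the conservation stage (alignment input)"
                )
            var_report = {}
            for vs in overlap_stats.read_variants(cfg.variants):
                intervals = hotspots.projections.get(vs.transcript_id, [])
                res = overlap_stats.hotspot_overlap(vs, intervals)
                var_report[vs.transcript_id] = {
                    "n_total": res.n_total,
                    "n_inside": res.n_inside,
                    "pct": res.pct,
                }
            (outdir / "variant_overlap.json").write_text(
                json.dumps(var_report, indent=2, sort_keys=True)
            )
            report["variants"] = var_report

    # -- lengths -------------------------------------------------------------
    with stage("lengths"):
        table = overlap_stats.summarize_lengths(records)
        table.summary().to_csv(outdir / "length_summary.tsv", sep="\t", index=False)
        mw_out = {}
        for section in cfg.mw_sections:
            groups_ok = [
                g for g in table.groups if len(table.lengths(g, section)) >= 2
            ]
            if len(groups_ok) < 2:
                logger.warning("section %s: fewer than 2 testable groups", section)
                continue
            mw = overlap_stats.pairwise_mw(table, section)
            mw.to_csv(outdir / f"mw_{section}.tsv", sep="\t", index=False)
            mw_out[section] = {
                f"{r.group1}|{r.group2}": round(r.p_corrected, 6)
                for r in mw.itertuples()
            }
        report["lengths"] = {
            "groups": table.groups,
            "mann_whitney_bonferroni": mw_out,
        }

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    _write_run_log(outdir, cfg)
    return report


def _write_run_log(outdir: Path, cfg: PipelineConfig) -> None:
    import datetime

    lines = [
        f"utrscope {__version__}",
        f"finished: {datetime.datetime.now().isoformat()}",
        "parameters:",
        cfg.defaults_yaml(),
    ]
    (outdir / "run.log").write_text("\n".join(lines))
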