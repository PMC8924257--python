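"""Candidate ranking, selection and the end-to-end design pipeline.

Guides are ranked by fewest off-target matches; ties break by PAM-to-edit
distance (cleavage close to the edit drives recombineering efficiency),
then by coordinate and strand so the ordering — and therefore every output
file — is fully deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .genome_io import (
    CdsFeature,
    EditSpec,
    GenomeSequence,
    genomes_by_name,
    write_fasta,
)
from .offtarget import DEFAULT_MISMATCH_THRESHOLD, GuideCandidate, count_offtargets
from .pam_scan import (
    DEFAULT_WINDOW,
    PamScanError,
    extract_n20,
    find_pam_sites,
    neighborhood,
)
from .template import (
    DEFAULT_TEMPLATE_LENGTH,
    RepairTemplate,
    TemplateError,
    build_template,
    ensure_cas9_escape,
)

log = logging.getLogger(__name__)

DEFAULT_SELECT = 6  # guides retained per edit


@dataclass(frozen=True)
class DesignConfig:
    """All knobs of the design pipeline, mirrored by the CLI and YAML config."""

    window: int = DEFAULT_WINDOW
    template_length: int = DEFAULT_TEMPLATE_LENGTH
    mismatch_threshold: int = DEFAULT_MISMATCH_THRESHOLD
    select: int = DEFAULT_SELECT
    require_pam_offtargets: bool = False
    escape_min_mismatches: int = 1
    template_strand: str = "+"


@dataclass
class DesignReport:
    """Everything the pipeline found for one edit."""

    edit: EditSpec
    candidates: list[GuideCandidate]
    selected: list[GuideCandidate]
    templates: list[RepairTemplate]  # parallel to selected
    warnings: list[str] = field(default_factory=list)


def pam_edit_distance(candidate: GuideCandidate, edit: EditSpec) -> int:
    """Gap in bases between the PAM triplet and the edit's reference interval.

    Zero when they overlap; used as the ranking tie-break.
    """
    pam_start = candidate.site.pam_start
    pam_end = pam_start + 3
    return max(0, pam_start - edit.end, edit.pos - pam_end)


def _rank_key(candidate: GuideCandidate, edit: EditSpec | None):
    distance = pam_edit_distance(candidate, edit) if edit is not None else 0
    return (
        candidate.offtarget_count,
        distance,
        candidate.site.pam_start,
        0 if candidate.site.strand == "+" else 1,
    )


def rank_and_select(
    candidates: Sequence[GuideCandidate],
    k: int,
    edit: EditSpec | None = None,
) -> list[GuideCandidate]:
    """The ``min(k, n)`` best candidates in deterministic order.

    Sort key: off-target count ascending, then PAM-to-edit distance, then
    pam_start, then strand (+ before -).  An empty candidate list yields an
    empty result (logged), so batch designs continue.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not candidates:
        log.warning("no candidates to select from")
        return []
    ranked = sorted(candidates, key=lambda c: _rank_key(c, edit))
    if k > len(ranked):
        log.warning("requested %d guides but only %d candidates exist", k, len(ranked))
    return ranked[:k]


def design_one(
    genomes: Sequence[GenomeSequence],
    edit: EditSpec,
    config: DesignConfig = DesignConfig(),
    cds: Sequence[CdsFeature] | None = None,
) -> DesignReport:
    """Run the full procedure for a single edit.

    neighborhood -> PAM scan -> N20 extraction -> off-target scoring ->
    ranking -> template construction -> Cas9-escape guarantee.  Candidates
    whose escape check fails (PAM outside the template) are dropped with a
    warning and the next-best candidate fills in.
    """
    warnings: list[str] = []
    index = genomes_by_name(genomes)
    genome = index[edit.contig]
    edit.validate_against(genome)

    region = neighborhood(edit, genome, window=config.window)
    if region.length < config.window:
        warnings.append(
            f"window clipped to [{region.start}, {region.end}) at contig bounds"
        )
    sites = find_pam_sites(genome, region)
    candidates: list[GuideCandidate] = []
    for site in sites:
        try:
            n20 = extract_n20(genome, site)
        except PamScanError as exc:
            warnings.append(str(exc))
            continue
        candidates.append(
            count_offtargets(
                genomes,
                n20,
                threshold=config.mismatch_threshold,
                require_pam=config.require_pam_offtargets,
            )
        )
    candidates.sort(key=lambda c: _rank_key(c, edit))
    if not candidates:
        warnings.append("no PAM in window")
        return DesignReport(edit, [], [], [], warnings)

    try:
        base_template = build_template(
            genome, edit, length=config.template_length, strand=config.template_strand
        )
    except TemplateError as exc:
        warnings.append(str(exc))
        return DesignReport(edit, candidates, [], [], warnings)

    selected: list[GuideCandidate] = []
    templates: list[RepairTemplate] = []
    for candidate in candidates:
        if len(selected) >= config.select:
            break
        try:
            templates.append(
                ensure_cas9_escape(
                    genome,
                    base_template,
                    candidate,
                    cds=cds,
                    escape_min_mismatches=config.escape_min_mismatches,
                )
            )
            selected.append(candidate)
        except TemplateError as exc:
            warnings.append(
                f"dropped candidate at pam_start={candidate.site.pam_start} "
                f"({candidate.site.strand}): {exc}"
            )
    if len(selected) < config.select:
        warnings.append(
            f"only {len(selected)} of {config.select} requested guides available"
        )
    return DesignReport(edit, candidates, selected, templates, warnings)


def design(
    genomes: Sequence[GenomeSequence],
    edits: Sequence[EditSpec],
    config: DesignConfig = DesignConfig(),
    cds: Sequence[CdsFeature] | None = None,
) -> list[DesignReport]:
    """Batch design: one report per edit; one bad edit never aborts the batch."""
    reports = []
    for edit in edits:
        log.info("designing guides for edit %r", edit.label)
        try:
            reports.append(design_one(genomes, edit, config, cds))
        except Exception as exc:  # per-edit failures are captured, not fatal
            log.error("edit %r failed: %s", edit.label, exc)
            reports.append(DesignReport(edit, [], [], [], [f"design failed: {exc}"]))
    return reports


# ---------------------------------------------------------------------------
# report serialization (deterministic byte-for-byte given identical inputs)

MAX_REPORTED_HITS = 50  # hit lists are truncated in the JSON report


def _candidate_dict(candidate: GuideCandidate) -> dict:
    return {
        "n20": candidate.n20.seq,
        "pam_start": candidate.site.pam_start,
        "pam_seq": candidate.site.pam_seq,
        "strand": candidate.site.strand,
        "protospacer_start": candidate.site.protospacer.start,
        "protospacer_end": candidate.site.protospacer.end,
        "offtarget_count": candidate.offtarget_count,
        "hits": [dataclasses.asdict(h) for h in candidate.hits[:MAX_REPORTED_HITS]],
        "hits_truncated": len(candidate.hits) > MAX_REPORTED_HITS,
    }


def report_to_dict(report: DesignReport) -> dict:
    return {
        "edit": dataclasses.asdict(report.edit),
        "candidates": [_candidate_dict(c) for c in report.candidates],
        "selected": [_candidate_dict(c) for c in report.selected],
        "templates": [
            {
                "seq": t.seq,
                "oligo": t.oligo,
                "contig": t.contig,
                "start": t.interval.start,
                "end": t.interval.end,
                "strand": t.strand,
                "edits_applied": [dataclasses.asdict(e) for e in t.edits_applied],
            }
            for t in report.templates
        ],
        "warnings": list(report.warnings),
    }


def write_reports_json(reports: Sequence[DesignReport], path: str | Path) -> None:
    payload = [report_to_dict(r) for r in reports]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _oligo_name(report: DesignReport, i: int) -> str:
    return f"{report.edit.label}_g{i + 1}"


def write_summary_tsv(reports: Sequence[DesignReport], path: str | Path) -> None:
    """One row per selected guide."""
    with open(path, "w") as fh:
        fh.write(
            "label\tcontig\tpam_start\tstrand\tn20\tofftarget_count\toligo_name\n"
        )
        for report in reports:
            for i, cand in enumerate(report.selected):
                fh.write(
                    f"{report.edit.label}\t{cand.site.contig}\t{cand.site.pam_start}"
                    f"\t{cand.site.strand}\t{cand.n20.seq}\t{cand.offtarget_count}"
                    f"\t{_oligo_name(report, i)}\n"
                )


def _edits_tag(template: RepairTemplate) -> str:
    return ",".join(
        f"{e.pos + 1}{e.ref}>{e.alt}:{e.reason}" for e in template.edits_applied
    )


def write_oligos_fasta(reports: Sequence[DesignReport], path: str | Path) -> None:
    """Repair oligos; header carries label, locus, strand and applied edits."""
    records = []
    for report in reports:
        for i, template in enumerate(report.templates):
            header = (
                f"{_oligo_name(report, i)}|{template.contig}"
                f"|{template.interval.start}-{template.interval.end}"
                f"|{template.strand}|{_edits_tag(template)}"
            )
            records.append((header, template.oligo))
    write_fasta(records, path)


def write_sites_bed(reports: Sequence[DesignReport], path: str | Path) -> None:
    """BED6 of selected protospacers; score column = off-target count."""
    with open(path, "w") as fh:
        for report in reports:
            for cand in report.selected:
                site = cand.site
                fh.write(
                    f"{site.contig}\t{site.protospacer.start}\t{site.protospacer.end}"
                    f"\t{report.edit.label}:{site.strand}:{site.pam_start}"
                    f"\t{cand.offtarget_count}\t{site.strand}\n"
                )
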