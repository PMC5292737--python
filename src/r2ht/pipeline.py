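"""End-to-end orchestration: characterize → distances → tree → HT report.

:func:`run_pipeline` wires the stages together from a
:class:`PipelineConfig` and writes the points CSV, regression JSON,
events JSON and a Markdown report.  Every stage failure is re-raised
with the stage name; all parameters and seeds are echoed into the
report for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .distances import build_matrix
from .elements import ElementRecord, characterize
from .hosts import DatedHostTree, parse_dated_newick
from .htmodel import (
    DEFAULT_LINEAGE_THRESHOLD,
    DEFAULT_PARALOG_CUTOFF,
    DEFAULT_T_FLAG,
    DivergenceAgeModel,
    topology_conflicts,
)
from .treebuild import (
    bootstrap_supports,
    calibrate_ages,
    midpoint_root,
    neighbor_joining,
    outgroup_root,
)


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; round-trips losslessly through JSON."""

    # inputs (either a distance table or an alignment)
    alignment_fasta: str | None = None
    aa_alignment_fasta: str | None = None
    distances_csv: str | None = None        # published-table layout
    mapping_csv: str | None = None
    host_newick: str | None = None
    indels_csv: str | None = None
    out_dir: str = "r2ht_out"
    # parameters
    t_flag: float = DEFAULT_T_FLAG
    flag_method: str = "residual"
    flag_scale: str = "mad"
    lineage_threshold: float = DEFAULT_LINEAGE_THRESHOLD
    paralog_cutoff: float = DEFAULT_PARALOG_CUTOFF
    l_min: int = 50
    s_min: float = 70.0
    bootstrap_reps: int = 100
    seed: int = 0
    outgroup: str | None = None
    calibrations: list = field(default_factory=list)
    explicit_exclude: list = field(default_factory=list)
    include_degenerate: bool = False
    include_intra_taxon: bool = False

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


def _load_inputs(cfg: PipelineConfig):
    if cfg.mapping_csv is None or cfg.host_newick is None:
        raise ValueError("mapping_csv and host_newick are required")
    mapping = io.read_mapping(cfg.mapping_csv)
    host = parse_dated_newick(Path(cfg.host_newick).read_text())
    nt = aa = None
    records = None
    if cfg.distances_csv is not None:
        nt, aa = io.read_published_table(cfg.distances_csv)
    elif cfg.alignment_fasta is not None:
        records = io.read_fasta(cfg.alignment_fasta)
        cov = io.coverage_from_mapping(mapping)
        degenerate = set(
            mapping.loc[mapping["degenerate"].astype(int) == 1,
                        "element_id"]
        )
        nt = build_matrix(records, "nt", coverage=cov,
                          degenerate=degenerate)
        if cfg.aa_alignment_fasta is not None:
            aa_records = io.read_fasta(cfg.aa_alignment_fasta)
            aa = build_matrix(aa_records, "aa", degenerate=degenerate)
    else:
        raise ValueError(
            "either distances_csv or alignment_fasta is required"
        )
    profiles = io.read_indel_profiles(cfg.indels_csv) \
        if cfg.indels_csv else None
    return records, nt, aa, mapping, host, profiles


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns a dict of output paths and key results."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        records, nt, aa, mapping, host, profiles = _load_inputs(cfg)
    except Exception as e:
        raise StageError("load", e)

    annotations = None
    if records is not None:
        try:
            annotations = [
                characterize(ElementRecord(
                    id=row.element_id, host_taxon=row.taxon,
                    seq=records[row.element_id].replace("-", "")
                    or records[row.element_id],
                ))
                for row in mapping.itertuples()
                if row.element_id in records
                and records[row.element_id].replace("-", "")
            ]
            pd.DataFrame(annotations).to_csv(
                out / "element_annotations.csv", index=False)
        except Exception as e:
            raise StageError("characterize", e)

    try:
        model = DivergenceAgeModel.from_distance_matrix(
            nt, mapping, host, aa_matrix=aa,
            include_intra_taxon=cfg.include_intra_taxon,
            include_degenerate=cfg.include_degenerate,
            paralog_cutoff=cfg.paralog_cutoff,
        )
        explicit = {
            frozenset(p) for p in cfg.explicit_exclude
        } or None
        results = model.fit(
            method=cfg.flag_method, t_flag=cfg.t_flag,
            scale=cfg.flag_scale, exclude=explicit,
        )
    except Exception as e:
        raise StageError("ht_detect", e)

    try:
        # the element tree keeps degenerate copies (their nucleotide
        # distances are fine and may anchor calibrations); only ancient
        # paralogs and records with uncomputable pairs are dropped
        paralogs = {
            e for e, why in model.points.excluded_elements.items()
            if why == "paralog"
        }
        tree_elements = [
            lab for lab in nt.labels
            if lab not in paralogs
            and all(nt.is_computed(lab, o) for o in nt.labels
                    if o != lab)
        ]
        sub = nt.submatrix(tree_elements)
        tree = neighbor_joining(sub)
        if records is not None:
            tree = bootstrap_supports(
                {k: records[k] for k in tree_elements},
                n_reps=cfg.bootstrap_reps, seed=cfg.seed, tree=tree,
            )
        if cfg.outgroup:
            tree = outgroup_root(tree, cfg.outgroup)
        else:
            tree = midpoint_root(tree)
        cals = [tuple(c) for c in cfg.calibrations]
        if cals:
            tree = calibrate_ages(tree, cals)
        (out / "element_tree.nwk").write_text(tree.to_newick() + "\n")
    except Exception as e:
        raise StageError("treebuild", e)

    try:
        events = results.reconstruct_events(
            tree, indel_profiles=profiles,
            lineage_threshold=cfg.lineage_threshold, s_min=cfg.s_min,
        )
        conflicts, rf = topology_conflicts(
            tree, host, mapping, s_min=cfg.s_min)
        lineages = results.lineage_partition(
            profiles, cfg.lineage_threshold)
    except Exception as e:
        raise StageError("events", e)

    # ---- outputs -------------------------------------------------------
    points_df = model.points.frame("nt")
    if aa is not None:
        aa_df = model.points.frame("aa").rename(columns={"d": "d_aa"})
        points_df = points_df.merge(
            aa_df[["a", "b", "d_aa"]], on=["a", "b"], how="left")
    points_df["flagged"] = [
        frozenset((r.a, r.b)) in results.flagged_pairs
        for r in points_df.itertuples()
    ]
    points_df.to_csv(out / "points.csv", index=False)

    regression = {
        resp: {
            "all": _reg_dict(fa), "excluded": _reg_dict(fe),
        }
        for resp, (fa, fe) in results.fits.items()
    }
    (out / "regression.json").write_text(
        json.dumps(regression, indent=1))

    events_json = [
        {
            "hub": e.hub,
            "partners": sorted(e.partners),
            "donor_taxa": sorted(e.donor_taxa),
            "recipient_taxa": sorted(e.recipient_taxa),
            "supporting_pairs": sorted(
                sorted(p) for p in e.supporting_pairs),
            "age_upper_bound_myr": e.age_upper_bound_myr,
            "criteria": e.criteria,
            "direction_is_heuristic": e.direction_is_heuristic,
        }
        for e in events
    ]
    (out / "events.json").write_text(json.dumps(events_json, indent=1))
    (out / "config.json").write_text(cfg.to_json())

    report = _markdown_report(cfg, results, events_json, conflicts, rf,
                              lineages)
    (out / "report.md").write_text(report)

    try:
        import matplotlib
        matplotlib.use("Agg")
        ax = results.plot()
        ax.figure.savefig(out / "divergence_vs_age.png", dpi=150)
    except Exception:
        pass  # plotting is best-effort; report and JSON are the record

    return {
        "out_dir": str(out),
        "results": results,
        "events": events,
        "n_events": len(events),
        "conflicts": conflicts,
        "rf": rf,
    }


def _reg_dict(r):
    return {"slope": r.slope, "intercept": r.intercept, "r2": r.r2,
            "pearson_r": r.pearson_r, "p_value": r.p_value,
            "n_points": r.n_points}


def _markdown_report(cfg, results, events_json, conflicts, rf, lineages):
    lines = [
        "# Horizontal-transfer screen report",
        "",
        "## Divergence vs. host split age",
        "",
        "```",
        results.summary(),
        "```",
        "",
        "## Lineage partition "
        f"(threshold {lineages.threshold:g}, shared large indels)",
        "",
    ]
    for b in lineages.blocks:
        lines.append(f"- {{{', '.join(sorted(b))}}}")
    lines += ["", f"## Topology conflicts (clade-RF = {rf})", ""]
    if conflicts:
        for c in conflicts:
            sup = c["support"]
            lines.append(
                f"- host clade {{{', '.join(sorted(c['host_clade']))}}} "
                f"vs element side {{{', '.join(sorted(c['element_side_taxa']))}}}"
                + (f" (support {sup:.0f}%)" if sup is not None else "")
            )
    else:
        lines.append("- none")
    lines += ["", f"## Reconstructed events: {len(events_json)}", ""]
    for e in events_json:
        crit = ", ".join(k for k, v in e["criteria"].items() if v)
        age = e["age_upper_bound_myr"]
        lines.append(
            f"- {'+'.join(e['donor_taxa'])} -> "
            f"{'+'.join(e['recipient_taxa'])} "
            f"(hub {e['hub']}; age <= "
            f"{age:.2f} Myr; criteria {crit})"
            if age is not None else
            f"- {'+'.join(e['donor_taxa'])} -> "
            f"{'+'.join(e['recipient_taxa'])} (hub {e['hub']}; "
            f"criteria {crit})"
        )
    lines += [
        "",
        "## Parameters",
        "",
        "```json",
        cfg.to_json(),
        "```",
        "",
    ]
    return "\n".join(lines)
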