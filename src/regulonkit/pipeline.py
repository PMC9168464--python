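"""End-to-end orchestration: counts -> QC -> activity -> RSS -> modules -> markers.

Every stage writes its table through the io module, so two runs with the same
inputs and seeds produce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as rio
from .activity import ActivityParams, score_activity
from .csi import (CSIParams, compute_csi, detect_modules, drop_zero_variance,
                  module_activity, pairwise_pcc, sankey_table)
from .datatypes import ActivityMatrix, CountMatrix, RegulonSet
from .markers import wilcoxon_markers
from .qc import QCParams, filter_cells, lognormalize, select_hvg
from .rss import compute_rss, positive_fraction, rank_masters

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline", "write_results"]


@dataclass(frozen=True)
class PipelineParams:
    qc: QCParams = QCParams()
    activity: ActivityParams = ActivityParams()
    csi: CSIParams = CSIParams()
    logfc_threshold: float = 0.25
    top_k_masters: int = 6
    top_k_sankey: int = 20
    run_markers: bool = True


@dataclass
class PipelineResult:
    qc_report: dict
    activity: ActivityMatrix
    rss: pd.DataFrame
    masters: pd.DataFrame
    positive_fraction: pd.DataFrame
    pcc: pd.DataFrame
    csi: pd.DataFrame
    modules: dict[str, str]
    module_by_type: pd.DataFrame
    module_per_cell: pd.DataFrame
    sankey: pd.DataFrame
    markers: pd.DataFrame | None
    excluded_regulons: dict[str, list[str]] = field(default_factory=dict)


def run_pipeline(
    counts: CountMatrix,
    annot: pd.DataFrame,
    regulons: RegulonSet,
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    filtered, annot_f, report = filter_cells(counts, annot, params.qc)
    norm = lognormalize(filtered, params.qc.scale_factor)
    select_hvg(norm, params.qc.n_hvg)

    activity = score_activity(norm, regulons, params.activity)
    rss, rss_excluded = compute_rss(activity, annot_f)
    masters = rank_masters(rss, params.top_k_masters)
    pos_frac = positive_fraction(activity, annot_f)

    act_var, pcc_excluded = drop_zero_variance(activity)
    pcc = pairwise_pcc(act_var)
    csi = compute_csi(pcc, params.csi.variant)
    n_modules = min(params.csi.n_modules, csi.shape[0])
    modules = detect_modules(
        csi,
        CSIParams(variant=params.csi.variant, linkage=params.csi.linkage,
                  n_modules=n_modules,
                  module_label_prefix=params.csi.module_label_prefix),
    )
    mod_by_type, mod_per_cell = module_activity(act_var, annot_f, modules)
    rss_var = rss.loc[[n for n in rss.index if n in modules]]
    sankey = sankey_table(rss_var, modules,
                          min(params.top_k_sankey, rss_var.shape[0]))

    marker_table = (
        wilcoxon_markers(norm, annot_f, params.logfc_threshold)
        if params.run_markers else None
    )
    return PipelineResult(
        qc_report=report,
        activity=activity,
        rss=rss,
        masters=masters,
        positive_fraction=pos_frac,
        pcc=pcc,
        csi=csi,
        modules=modules,
        module_by_type=mod_by_type,
        module_per_cell=mod_per_cell,
        sankey=sankey,
        markers=marker_table,
        excluded_regulons={
            "below_presence_minimum": activity.excluded,
            "zero_activity": rss_excluded,
            "zero_variance": pcc_excluded,
        },
    )


def write_results(result: PipelineResult, directory: str | Path) -> None:
    """Write every table of a pipeline run as TSV/JSON under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rio.write_json(result.qc_report, directory / "qc_report.json")
    rio.write_table(result.activity.to_frame(), directory / "activity.tsv")
    rio.write_table(result.rss, directory / "rss.tsv")
    rio.write_table(result.masters, directory / "masters.tsv", index=False)
    rio.write_table(result.positive_fraction,
                    directory / "positive_fraction.tsv")
    rio.write_table(result.pcc, directory / "pcc.tsv")
    rio.write_table(result.csi, directory / "csi.tsv")
    assignment = pd.DataFrame(
        {"regulon": list(result.modules), "module": list(result.modules.values())}
    )
    rio.write_table(assignment, directory / "modules.tsv", index=False)
    rio.write_table(result.module_by_type, directory / "module_activity.tsv")
    rio.write_table(result.module_per_cell,
                    directory / "module_per_cell.tsv")
    rio.write_table(result.sankey, directory / "sankey.tsv", index=False)
    if result.markers is not None:
        rio.write_table(result.markers, directory / "markers.tsv", index=False)
    rio.write_json(result.excluded_regulons,
                   directory / "excluded_regulons.json")
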