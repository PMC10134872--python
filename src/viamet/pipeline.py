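"""End-to-end analysis pipeline: qPCR -> loads -> abundances -> diversity.

Orchestrates the analysis stages over one study directory (real exports or
:func:`viamet.simulate.write_study` output) and writes a report bundle:

* ``standard_curve.json`` — fitted slope/intercept/efficiency/R^2
* ``loads.csv``           — per-sample microbiota loads
* ``depletion.csv``       — spike-strain and host-marker removal percentages
* ``host_fraction.csv``   — host-read proportions (spike-ins excluded)
* ``load_summary.csv``    — per-host survival and mean killed percentages
* ``alpha_diversity.csv`` — Shannon/Simpson per sample
* ``bray_curtis_<type>.tsv``, ``pcoa_<type>.csv``, ``anosim_<type>.json``
* ``fold_changes_<type>_<contrast>.csv`` — classified species responses
* ``summary.json``        — machine-readable digest of all of the above

Every stage logs its inputs and parameters to stderr; any failure aborts
with the stage name (and offending sample where known).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import abundance as ab
from . import diversity as dv
from . import io as vio
from . import qpcr as qp
from .errors import InvalidInputError, ViametError
from .simulate import SPIKE_STRAINS

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("viamet")

#: Contrast -> (treated group, classification preset by sample type)
_CONTRASTS = {
    "lyPMAxx": ("lyPMAxx", {"saliva": "lyPMAxx", "feces": "lyPMAxx"}),
    "freezing": (
        "frozen_lyPMAxx",
        {"saliva": "freezing_saliva", "feces": "freezing_feces"},
    ),
}

_DEAD_SPIKES = [s["name"] for s in SPIKE_STRAINS if s["status"] == "dead"]
_SPIKE_NAMES = [s["name"] for s in SPIKE_STRAINS]


class PipelineError(ViametError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Pipeline run settings.

    ``input_dir`` must contain metadata.csv, qpcr.csv, standard_curve.csv,
    read_accounting.csv and taxon_<type>.tsv. ``conversion`` maps sample
    types to reaction->unit conversion blocks (see
    :func:`viamet.io.read_conversion_config`); without it the pipeline
    refuses to compute per-mL/per-g loads.
    """

    input_dir: str
    output_dir: str
    conversion: Mapping[str, Mapping] = field(default_factory=dict)
    seed: int = 0
    permutations: int = 999
    spike_taxa: tuple[str, ...] = tuple(_SPIKE_NAMES)
    efficiency_from_curve: bool = False  # default: perfect doubling (E = 1)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, Mapping):
            raise InvalidInputError("run config must be a mapping")
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise InvalidInputError(f"unknown run-config keys: {sorted(bad)}")
        if "spike_taxa" in raw:
            raw = {**raw, "spike_taxa": tuple(raw["spike_taxa"])}
        return cls(**raw)


# Default bookkeeping when none is supplied: 1 uL of a 50-uL eluate from one
# sample unit, no predilution (matches the simulator's template fraction).
_DEFAULT_CONVERSION = {
    "saliva": dict(reaction_input_volume_ul=1.0, elution_volume_ul=50.0,
                   sample_amount=1.0, sample_unit="per_mL", dilution_factor=1.0),
    "feces": dict(reaction_input_volume_ul=1.0, elution_volume_ul=50.0,
                  sample_amount=1.0, sample_unit="per_g", dilution_factor=1.0),
}


def _mean_ct(measurements, sample_ids, assay):
    """Pooled mean Ct over all uncensored wells of an assay across samples."""
    cts = [
        m.ct
        for m in measurements
        if m.assay == assay and m.sample_id in sample_ids and not m.censored
    ]
    return (float(np.mean(cts)), len(cts)) if cts else (None, 0)


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns the summary dict (also written to ``summary.json``). Determinism:
    the only stochastic stage (ANOSIM permutations) uses ``config.seed``.
    """
    indir, outdir = Path(config.input_dir), Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "input_dir": str(indir)}

    stage = "load-inputs"
    try:
        records = vio.read_metadata_csv(indir / "metadata.csv")
        measurements = vio.read_qpcr_csv(indir / "qpcr.csv")
        curve_points = vio.read_standard_curve_csv(indir / "standard_curve.csv")
        accounting = vio.read_read_accounting_csv(indir / "read_accounting.csv")
        sample_types = sorted({r.sample_type for r in records})
        tables = {
            st: ab.read_taxon_table(indir / f"taxon_{st}.tsv") for st in sample_types
        }
        log.info("loaded %d samples, %d qPCR wells, %d sample types",
                 len(records), len(measurements), len(sample_types))
    except (OSError, ViametError) as e:
        raise PipelineError(stage, str(e)) from e

    stage = "standard-curve"
    try:
        curve = qp.fit_standard_curve(curve_points)
        efficiency = curve.efficiency if config.efficiency_from_curve else 1.0
        log.info("standard curve: slope=%.4f intercept=%.3f E=%.3f (using E=%.3f)",
                 curve.slope, curve.intercept, curve.efficiency, efficiency)
        (outdir / "standard_curve.json").write_text(json.dumps(dict(
            slope=round(curve.slope, 6), intercept=round(curve.intercept, 6),
            r_squared=round(curve.r_squared, 6),
            efficiency=round(curve.efficiency, 6),
            efficiency_used=efficiency), indent=2))
        summary["standard_curve"] = dict(
            slope=round(curve.slope, 4), efficiency=round(curve.efficiency, 4)
        )
    except ViametError as e:
        raise PipelineError(stage, str(e)) from e

    by_sample = {r.sample_id: r for r in records}
    conversion = dict(_DEFAULT_CONVERSION)
    conversion.update({k: dict(v) for k, v in config.conversion.items()})

    stage = "microbiota-loads"
    try:
        loads: dict[str, qp.MicrobiotaLoad] = {}
        for r in records:
            ct, n = _mean_ct(measurements, {r.sample_id}, "universal_16S")
            if ct is None:
                raise InvalidInputError(
                    f"sample {r.sample_id}: all universal_16S wells censored"
                )
            conv = conversion[r.sample_type]
            loads[r.sample_id] = qp.microbiota_load(
                qp.ct_to_copies(ct, curve),
                conv["reaction_input_volume_ul"], conv["elution_volume_ul"],
                conv["sample_amount"], conv["sample_unit"],
                conv["dilution_factor"], sample_id=r.sample_id,
            )
        vio.write_loads_csv(loads, outdir / "loads.csv")
    except ViametError as e:
        raise PipelineError(stage, str(e)) from e

    stage = "depletion"
    try:
        depletion_rows = []
        hosts = sorted({r.host_id for r in records})
        for st in sample_types:
            for host in hosts:
                ids_ctrl = {r.sample_id for r in records
                            if r.host_id == host and r.sample_type == st
                            and r.group == "control"}
                ids_trt = {r.sample_id for r in records
                           if r.host_id == host and r.sample_type == st
                           and r.group == "lyPMAxx"}
                if not ids_ctrl or not ids_trt:
                    continue
                for assay in [*_DEAD_SPIKES, "host_marker"]:
                    ct_c, n_c = _mean_ct(measurements, ids_ctrl, assay)
                    ct_t, n_t = _mean_ct(measurements, ids_trt, assay)
                    if ct_c is None:
                        continue  # target absent pre-treatment: nothing to deplete
                    res = qp.depletion_efficiency(
                        ct_c, ct_t, efficiency,
                        assay=assay, treated_censored=ct_t is None,
                    )
                    depletion_rows.append(dict(
                        sample_type=st, host_id=host, assay=assay,
                        ct_control=round(res.ct_control, 4),
                        ct_treated=round(res.ct_treated, 4),
                        percent_removed=res.percent_removed,
                        censored_bound=res.censored_bound,
                        n_control_wells=n_c, n_treated_wells=n_t,
                    ))
        depl = pd.DataFrame(depletion_rows)
        depl.to_csv(outdir / "depletion.csv", index=False)
        summary["depletion_percent"] = {
            st: {
                assay: round(float(g["percent_removed"].mean()), 2)
                for assay, g in depl[depl.sample_type == st].groupby("assay")
            }
            for st in sample_types
        } if len(depl) else {}
    except ViametError as e:
        raise PipelineError(stage, str(e)) from e

    stage = "host-fraction"
    try:
        rows = []
        for acct in accounting:
            r = by_sample.get(acct.sample_id)
            if r is None:
                raise InvalidInputError(f"accounting for unknown sample {acct.sample_id}")
            rows.append(dict(
                sample_id=acct.sample_id, sample_type=r.sample_type, group=r.group,
                host_fraction=round(ab.host_read_fraction(acct), 6),
            ))
        hf = pd.DataFrame(rows)
        hf.to_csv(outdir / "host_fraction.csv", index=False)
        summary["host_read_percent"] = {
            st: {
                grp: round(100 * float(g["host_fraction"].mean()), 2)
                for grp, g in hf[hf.sample_type == st].groupby("group")
            }
            for st in sample_types
        }
    except ViametError as e:
        raise PipelineError(stage, str(e)) from e

    stage = "load-summary"
    try:
        rows = []
        summary["mean_killed_percent"] = {}
        for st in sample_types:
            for contrast, (treated_group, _) in _CONTRASTS.items():
                survivals = []
                for host in hosts:
                    def _mean_load(group):
                        vals = [loads[r.sample_id].copies_per_unit for r in records
                                if r.host_id == host and r.sample_type == st
                                and r.group == group]
                        return float(np.mean(vals)) if vals else None
                    ctrl, trt = _mean_load("control"), _mean_load(treated_group)
                    if ctrl is None or trt is None:
                        continue
                    unit = conversion[st]["sample_unit"]
                    surv = qp.survival_percent(
                        qp.MicrobiotaLoad(f"{host}", trt, unit),
                        qp.MicrobiotaLoad(f"{host}", ctrl, unit),
                    )
                    survivals.append(surv)
                    rows.append(dict(sample_type=st, host_id=host,
                                     contrast=contrast, survival_percent=surv))
                if survivals:
                    mk = qp.mean_killed_percent(
                        [min(s, 100.0) for s in survivals], rounding="one_decimal"
                    )
                    summary["mean_killed_percent"].setdefault(st, {})[contrast] = mk
        pd.DataFrame(rows).to_csv(outdir / "load_summary.csv", index=False)
    except ViametError as e:
        raise PipelineError(stage, str(e)) from e

    stage = "diversity"
    try:
        alpha_rows = []
        summary["anosim_by_host"] = {}
        summary["intra_vs_inter"] = {}
        stripped: dict[str, ab.TaxonTable] = {}
        for st in sample_types:
            table, removed = ab.strip_spikeins(tables[st], config.spike_taxa)
            species = table.species_level()
            stripped[st] = species
            for sid in species.sample_ids:
                p = species.data[sid].to_numpy()
                alpha_rows.append(dict(
                    sample_id=sid, sample_type=st,
                    shannon=round(dv.shannon(p), 6),
                    simpson=round(dv.simpson(p), 6),
                ))
            dm = dv.beta_diversity_matrix(species.data)
            vio.write_distance_matrix_tsv(dm, outdir / f"bray_curtis_{st}.tsv")
            ord_res = dv.pcoa(dm, n_axes=2)
            vio.write_ordination_csv(ord_res, outdir / f"pcoa_{st}.csv")
            host_of = {r.sample_id: r.host_id for r in records}
            ares = dv.anosim(
                dm, [host_of[s] for s in dm.ids],
                n_permutations=config.permutations, seed=config.seed,
            )
            vio.write_anosim_json(ares, outdir / f"anosim_{st}.json")
            summary["anosim_by_host"][st] = dict(
                R=round(ares.r_statistic, 3), p=round(ares.p_value, 4)
            )
            ii = dv.intra_inter_comparison(dm, [host_of[s] for s in dm.ids])
            summary["intra_vs_inter"][st] = dict(
                median_intra=round(ii.median_intra, 4),
                median_inter=round(ii.median_inter, 4),
                p=round(ii.p_value, 6),
            )
        pd.DataFrame(alpha_rows).to_csv(outdir / "alpha_diversity.csv", index=False)
        alpha = pd.DataFrame(alpha_rows)
        grp_of = {r.sample_id: r.group for r in records}
        alpha["group"] = alpha["sample_id"].map(grp_of)
        summary["alpha_shannon_mean"] = {
            st: {grp: round(float(g["shannon"].mean()), 4)
                 for grp, g in alpha[alpha.sample_type == st].groupby("group")}
            for st in sample_types
        }
    except ViametError as e:
        raise PipelineError(stage, str(e)) from e

    stage = "fold-changes"
    try:
        summary["shared_species"] = {}
        summary["fold_change_classes"] = {}
        for st in sample_types:
            species = stripped[st]
            abs_table = ab.absolute_abundance(species, loads)
            shared = ab.shared_species(species, records, st)
            summary["shared_species"][st] = len(shared)
            for contrast, (treated_group, presets) in _CONTRASTS.items():
                if not any(r.group == treated_group for r in records):
                    continue
                fc = ab.species_fold_change(
                    abs_table, records, "control", treated_group, species=shared
                )
                fc = ab.classify_response(fc, presets[st])
                vio.write_fold_changes_csv(
                    fc, outdir / f"fold_changes_{st}_{contrast}.csv"
                )
                classes = pd.Series([r.response_class for r in fc])
                n_sig = sum(
                    1 for r in fc
                    if not np.isnan(r.p_value) and r.p_value < 0.05
                    and r.fold_change > 1
                )
                summary["fold_change_classes"][f"{st}_{contrast}"] = dict(
                    classes.value_counts().astype(int).to_dict(),
                    n_significant_declines=n_sig,
                )
        log.info("fold-change stage done")
    except ViametError as e:
        raise PipelineError(stage, str(e)) from e

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
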