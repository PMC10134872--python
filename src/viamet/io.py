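"""Readers and writers for the package's tabular dialects.

Input dialects:

* qPCR plate CSV — header ``sample_id,assay,replicate,ct``; an empty ``ct``
  field marks a censored (no-amplification) well.
* standard-curve CSV — header ``log10_copies,ct``.
* metadata CSV — ``sample_id,host_id,sample_type,group,replicate``.
* read-accounting CSV — ``sample_id,host_reads,microbial_reads,spikein_reads``.
* conversion config — YAML or JSON with, per sample type, the keys
  ``reaction_input_volume_ul``, ``elution_volume_ul``, ``sample_amount``,
  ``sample_unit`` and ``dilution_factor``. Loads are never emitted without
  an explicit conversion config.
* taxon table TSV — see :func:`viamet.abundance.read_taxon_table`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .abundance import FoldChangeResult, ReadAccounting, SampleRecord
from .diversity import AnosimResult, DistanceMatrix, OrdinationResult
from .errors import InvalidConfigError, InvalidInputError
from .qpcr import MicrobiotaLoad, QpcrMeasurement

__all__ = [
    "read_qpcr_csv",
    "read_standard_curve_csv",
    "read_metadata_csv",
    "read_read_accounting_csv",
    "read_conversion_config",
    "write_loads_csv",
    "write_fold_changes_csv",
    "write_distance_matrix_tsv",
    "read_distance_matrix_tsv",
    "write_ordination_csv",
    "write_anosim_json",
]

_CONVERSION_KEYS = {
    "reaction_input_volume_ul",
    "elution_volume_ul",
    "sample_amount",
    "sample_unit",
    "dilution_factor",
}


def read_qpcr_csv(path) -> list[QpcrMeasurement]:
    df = pd.read_csv(path, dtype={"sample_id": str, "assay": str})
    required = {"sample_id", "assay", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"qPCR CSV missing columns: {sorted(missing)}")
    out = []
    for r in df.itertuples():
        censored = pd.isna(r.ct) or r.ct == ""
        out.append(
            QpcrMeasurement(
                sample_id=r.sample_id,
                assay=r.assay,
                ct=None if censored else float(r.ct),
                replicate=int(r.replicate),
                censored=censored,
            )
        )
    return out


def read_standard_curve_csv(path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    missing = {"log10_copies", "ct"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"standard-curve CSV missing columns: {sorted(missing)}")
    return list(zip(df["log10_copies"].astype(float), df["ct"].astype(float)))


def read_metadata_csv(path) -> list[SampleRecord]:
    df = pd.read_csv(path, dtype=str)
    missing = {"sample_id", "host_id", "sample_type", "group", "replicate"} - set(
        df.columns
    )
    if missing:
        raise InvalidInputError(f"metadata CSV missing columns: {sorted(missing)}")
    records = [
        SampleRecord(
            sample_id=r.sample_id, host_id=r.host_id, sample_type=r.sample_type,
            group=r.group, replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]
    keys = [(r.host_id, r.sample_type, r.group, r.replicate) for r in records]
    if len(set(keys)) != len(keys):
        raise InvalidInputError("duplicate (host, sample_type, group, replicate) keys")
    return records


def read_read_accounting_csv(path) -> list[ReadAccounting]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = {"sample_id", "host_reads", "microbial_reads"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"read-accounting CSV missing: {sorted(missing)}")
    if "spikein_reads" not in df.columns:
        df["spikein_reads"] = 0
    return [
        ReadAccounting(
            sample_id=r.sample_id, host_reads=int(r.host_reads),
            microbial_reads=int(r.microbial_reads),
            spikein_reads=int(r.spikein_reads),
        )
        for r in df.itertuples()
    ]


def read_conversion_config(path) -> dict[str, dict]:
    """Load and validate the reaction->sample-unit conversion config.

    The file maps sample types to conversion-factor blocks; a flat block is
    accepted and applied to every sample type.
    """
    p = Path(path)
    raw = (
        json.loads(p.read_text())
        if p.suffix == ".json"
        else yaml.safe_load(p.read_text())
    )
    if not isinstance(raw, Mapping):
        raise InvalidConfigError("conversion config must be a mapping", str(path))
    if _CONVERSION_KEYS & set(raw):  # flat form
        raw = {"saliva": dict(raw), "feces": dict(raw)}
    out = {}
    for stype, block in raw.items():
        missing = _CONVERSION_KEYS - set(block)
        if missing:
            raise InvalidConfigError(
                f"missing keys {sorted(missing)}", f"conversion.{stype}"
            )
        if block["sample_unit"] not in ("per_mL", "per_g"):
            raise InvalidConfigError(
                f"sample_unit must be per_mL or per_g, got {block['sample_unit']!r}",
                f"conversion.{stype}",
            )
        out[stype] = {k: block[k] for k in _CONVERSION_KEYS}
    return out


def write_loads_csv(loads: Mapping[str, MicrobiotaLoad], path) -> None:
    pd.DataFrame(
        [
            dict(sample_id=sid, copies_per_unit=f"{ld.copies_per_unit:.6g}",
                 unit=ld.unit, dilution_factor=ld.dilution_factor)
            for sid, ld in loads.items()
        ]
    ).to_csv(path, index=False)


def write_fold_changes_csv(results: list[FoldChangeResult], path) -> None:
    pd.DataFrame(
        [
            dict(species=r.species,
                 mean_abs_control=f"{r.mean_abs_control:.6g}",
                 mean_abs_treated=f"{r.mean_abs_treated:.6g}",
                 fold_change=f"{r.fold_change:.6g}",
                 p_value=f"{r.p_value:.6g}",
                 response_class=r.response_class,
                 pseudocount_used=r.pseudocount_used,
                 n_pairs=r.n_pairs)
            for r in results
        ]
    ).to_csv(path, index=False)


def write_distance_matrix_tsv(d: DistanceMatrix, path) -> None:
    pd.DataFrame(d.data, index=list(d.ids), columns=list(d.ids)).to_csv(path, sep="\t")


def read_distance_matrix_tsv(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), list(df.columns))


def write_ordination_csv(res: OrdinationResult, path) -> None:
    df = res.coordinates.copy()
    df.index.name = "sample_id"
    header = "# eigenvalues: " + ",".join(f"{v:.6g}" for v in res.eigenvalues)
    header += "\n# proportion_explained: " + ",".join(
        f"{v:.6g}" for v in res.proportion_explained
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh)


def write_anosim_json(res: AnosimResult, path) -> None:
    Path(path).write_text(
        json.dumps(
            dict(R=round(res.r_statistic, 6), p=round(res.p_value, 6),
                 n_permutations=res.n_permutations, seed=res.seed),
            indent=2,
        )
    )
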