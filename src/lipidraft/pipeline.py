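"""End-to-end orchestration: identify -> quantify -> compose (-> compare) -> NMR.

Every stage writes its TSV next to the others in the output directory, the
fully resolved configuration is echoed alongside, and a JSON run summary
records counts in/out of each stage plus (when a ground-truth table is
supplied) identification precision/recall.  All outputs are deterministic:
the same config and inputs give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import composition as comp
from . import features as fio
from .identify import (
    Identification,
    ScoringParams,
    identify as run_identification,
    write_identifications,
)
from . import library as lib
from . import nmr
from . import quantify as quant
from .errors import LipidraftError, StageError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    library_path: str
    features_path: str
    spectra_path: str
    samples_path: str
    outdir: str
    params: ScoringParams = field(default_factory=ScoringParams)
    compare: tuple[str, str] | None = ("raft", "nonraft")
    truth_path: str | None = None
    nmr_condition_path: str | None = None
    nmr_reference_path: str | None = None
    nmr_control_profile_path: str | None = None
    nmr_reference_residue: int = 5
    log_level: str = "INFO"
    seed: int = 0


def read_truth_table(path) -> dict[str, str]:
    """Read a `feature_id<TAB>species_id` ground-truth map."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["feature_id"], df["species_id"]))


def write_truth_table(feature_truth: dict[str, str], path) -> None:
    import pandas as pd

    pd.DataFrame(
        sorted(feature_truth.items()), columns=["feature_id", "species_id"]
    ).to_csv(path, sep="\t", index=False)


def precision_recall(
    identifications: list[Identification], feature_truth: dict[str, str]
) -> tuple[float, float]:
    """Identification precision/recall over features with a true species.

    Accepted matches to the true species are TP; accepted matches to a wrong
    species — or to features that are truly unknown — are FP; identifiable
    features with no accepted match are FN.
    """
    accepted = {i.feature_id: i.species_id for i in identifications if i.accepted}
    tp = fp = fn = 0
    for fid, true_species in feature_truth.items():
        got = accepted.pop(fid, None)
        if true_species == "unknown":
            if got is not None:
                fp += 1
            continue
        if got is None:
            fn += 1
        elif got == true_species:
            tp += 1
        else:
            fp += 1
    fp += len(accepted)  # accepted features absent from the truth table
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return precision, recall


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full post-detection workflow; returns the run summary."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}, "seed": config.seed}

    _echo_config(config, outdir / "resolved_config.yaml")

    stage = "load"
    try:
        library = lib.read_library(config.library_path)
        features = fio.read_features(config.features_path, config.spectra_path)
        samples = fio.read_sample_meta(config.samples_path)
        summary["stages"]["load"] = {
            "library_entries": len(library),
            "features": len(features),
            "features_with_ms2": sum(f.ms2 is not None for f in features),
            "samples": len(samples),
        }

        stage = "identify"
        logger.info("stage=identify features=%d library=%d", len(features), len(library))
        identifications = run_identification(features, library, config.params)
        write_identifications(identifications, outdir / "id.tsv")
        n_accepted = sum(i.accepted for i in identifications)
        summary["stages"]["identify"] = {
            "candidates_scored": len(identifications),
            "accepted": n_accepted,
        }
        if config.truth_path:
            truth = read_truth_table(config.truth_path)
            precision, recall = precision_recall(identifications, truth)
            summary["stages"]["identify"]["precision"] = precision
            summary["stages"]["identify"]["recall"] = recall

        stage = "quantify"
        records = quant.build_quant_table(identifications, features, samples, library)
        quant.write_quant_table(records, outdir / "quant.tsv")
        summary["stages"]["quantify"] = {
            "records": len(records),
            "errors": sum(r.error is not None for r in records),
        }

        stage = "compose"
        if records:
            profiles = comp.subclass_composition(records, library)
            comp.write_composition(profiles, outdir / "comp.tsv")
            summary["stages"]["compose"] = {"samples": len(profiles)}
            if config.compare is not None:
                group_a, group_b = config.compare
                by_group = {s.sample_id: s.group for s in samples}
                prof_a = [p for p in profiles if by_group.get(p.sample_id) == group_a]
                prof_b = [p for p in profiles if by_group.get(p.sample_id) == group_b]
                if len(prof_a) >= 2 and len(prof_b) >= 2:
                    comparisons = comp.compare_groups(prof_a, prof_b)
                    comp.write_comparison(
                        comparisons, outdir / "compare.tsv",
                        label_a=group_a, label_b=group_b,
                    )
                    summary["stages"]["compare"] = {
                        "subclasses": len(comparisons),
                        "significant": sum(
                            c.significance_label != "n.s." for c in comparisons
                        ),
                    }
        else:
            comp.write_composition([], outdir / "comp.tsv")
            summary["stages"]["compose"] = {"samples": 0}

        if config.nmr_condition_path and config.nmr_reference_path:
            stage = "nmr"
            cond = nmr.read_peak_table(config.nmr_condition_path, "condition")
            ref = nmr.read_peak_table(config.nmr_reference_path, "reference")
            profile = nmr.relative_intensity_profile(
                cond, ref, config.nmr_reference_residue
            )
            if config.nmr_control_profile_path:
                control = nmr.read_profile(
                    config.nmr_control_profile_path, config.nmr_reference_residue
                )
                nmr.relative_change(profile, control)
            nmr.write_profile(profile, outdir / "nmr_profile.tsv")
            summary["stages"]["nmr"] = {
                "residues_defined": sum(v is not None for v in profile.y.values()),
                "disappeared": sum(profile.disappeared.values()),
            }
    except LipidraftError as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(stage, str(exc)) from exc

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _echo_config(config: RunConfig, path: Path) -> None:
    resolved = dataclasses.asdict(config)
    resolved["compare"] = list(config.compare) if config.compare else None
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
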