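"""End-to-end pipeline: simulate or load a screen, estimate, score, compare.

One call produces a reproducible report bundle in an output directory:
isolate tables, propensity tables, extracted scales, the cross-scale
comparison, and a run log carrying the seed, package version, config echo
and config hash. Identical config + seed yields a byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

from . import __version__
from .compare import compare_scales
from .library_sim import (
    PhenotypeModel,
    calibrate_theta,
    read_isolates,
    simulate_screen,
    write_isolates,
)
from .propensity import (
    AminoAcidScale,
    EstimationError,
    count_residues,
    build_propensity_table,
    score_to_scale,
    write_propensity_table,
)
from .screen import ScreenConfig, partition_libraries
from .seqcore import nnb_scheme, uniform_codon_scheme
from .tables import papa_scale, published_scale


class ConfigurationError(ValueError):
    """The pipeline config is missing or misusing keys."""


_SCHEMES = {"nnb": nnb_scheme, "nnn": uniform_codon_scheme}


def resolve_scale(spec: str) -> AminoAcidScale:
    """A scale from a bundled name or a user JSON file path."""
    if spec.endswith(".json") or "/" in spec:
        return AminoAcidScale.from_json(spec)
    return published_scale(spec)


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: Mapping[str, Any]) -> dict[str, Path]:
    """Run the configured analysis; returns a name -> path map of outputs.

    Config keys: ``mode`` ("simulate" or "load"), ``outdir``; for
    simulate additionally ``n`` and ``seed`` (optional: ``scheme``,
    ``scale``, ``prion_scale``, ``theta``, ``tau``, ``mu_pos``,
    ``mu_neg``, ``prion_max``, ``window_len``, ``target_positive_fraction``);
    for load, ``isolates`` (a TSV path). Unknown modes and missing keys
    raise :class:`ConfigurationError` naming the absent keys.
    """
    required = {"mode", "outdir"}
    mode = config.get("mode")
    if mode == "simulate":
        required |= {"n", "seed"}
    elif mode == "load":
        required |= {"isolates"}
    elif mode is not None:
        raise ConfigurationError(f"unknown mode {mode!r}; expected 'simulate' or 'load'")
    missing = sorted(k for k in required if k not in config)
    if missing:
        raise ConfigurationError(f"missing config keys: {missing}")

    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    screen_config = ScreenConfig(colony_threshold=int(config.get("colony_threshold", 5)))

    if mode == "simulate":
        scheme = _SCHEMES[config.get("scheme", "nnb")]()
        true_scale = resolve_scale(config.get("scale", "a2_degradation"))
        prion_scale = resolve_scale(config.get("prion_scale", "a2_prion"))
        tau = float(config.get("tau", 1.0))
        seed = int(config["seed"])
        if "theta" in config:
            theta = float(config["theta"])
        else:
            theta = calibrate_theta(
                true_scale,
                scheme,
                target_positive_fraction=float(config.get("target_positive_fraction", 0.35)),
                tau=tau,
                seed=seed,
            )
        model = PhenotypeModel(
            true_scale=true_scale,
            theta=theta,
            tau=tau,
            mu_pos=float(config.get("mu_pos", 20.0)),
            mu_neg=float(config.get("mu_neg", 1.0)),
            prion_scale=prion_scale,
            prion_max=float(config.get("prion_max", 0.1)),
        )
        ade_plus, ade_minus, prion = simulate_screen(
            scheme,
            int(config["n"]),
            model,
            seed=seed,
            window_len=int(config.get("window_len", 8)),
            config=screen_config,
        )
        outputs["isolates"] = outdir / "isolates.tsv"
        write_isolates(ade_plus + ade_minus + prion, outputs["isolates"])
    else:
        records = read_isolates(config["isolates"])
        ade_plus, ade_minus, prion = partition_libraries(records, screen_config)
        seed = int(config.get("seed", 0))

    if not ade_plus or not ade_minus:
        raise EstimationError(
            f"cannot estimate propensities from {len(ade_plus)} ADE+ and "
            f"{len(ade_minus)} ade- isolates"
        )

    ref_counts = count_residues([r.peptide for r in ade_minus])
    deg_table = build_propensity_table(
        count_residues([r.peptide for r in ade_plus]),
        ref_counts,
        scale_kind="degradation",
        context="simulated" if mode == "simulate" else "loaded",
    )
    outputs["degradation_table"] = outdir / "degradation_table.tsv"
    write_propensity_table(deg_table, outputs["degradation_table"])
    deg_scale = score_to_scale(deg_table, name="estimated_degradation")
    outputs["degradation_scale"] = outdir / "degradation_scale.json"
    deg_scale.to_json(outputs["degradation_scale"])

    if prion:
        prion_table = build_propensity_table(
            count_residues([r.peptide for r in prion]),
            ref_counts,
            scale_kind="prion",
            context=deg_table.attrs["context"],
        )
        outputs["prion_table"] = outdir / "prion_table.tsv"
        write_propensity_table(prion_table, outputs["prion_table"])

    comparison = compare_scales(papa_scale(), deg_scale)
    outputs["comparison"] = outdir / "comparison.tsv"
    comparison.table.assign(rho=comparison.rho, p_rho=comparison.p_rho).to_csv(
        outputs["comparison"], sep="\t", index=False, float_format="%.6g"
    )

    log = {
        "package_version": __version__,
        "seed": seed,
        "config": dict(config),
        "config_hash": _config_hash(config),
        "library_sizes": {
            "ade_plus": len(ade_plus),
            "ade_minus": len(ade_minus),
            "prion": len(prion),
        },
        "outputs": {name: path.name for name, path in outputs.items()},
    }
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True, default=str) + "\n")
    outputs["run_log"] = log_path
    return outputs
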