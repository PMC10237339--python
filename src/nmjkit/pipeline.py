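"""End-to-end synthetic study orchestration (simulate -> analyze -> stats).

A :class:`StudyConfig` fixes the design (ages, genotypes, group sizes) and a
master seed; every stage derives its own seed as a stable hash of
``(master_seed, stage, group, replicate)``, so the whole bundle is
reproducible bit-for-bit and no two stages share a random stream.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .ephys_analysis import detect_mepps, measure_epps, measure_train, summarize_nmj
from .ephys_sim import (build_scenario, evoked_protocol, simulate_recording,
                        simulate_train, spontaneous_protocol)
from .image_sim import build_image_scenario, generate_nmj, truth_manifest_row
from .morphometry import analyze_image
from .stats_report import build_report

__all__ = ["StudyConfig", "derive_seed", "run_study", "simulate_ephys_group"]


def derive_seed(master_seed: int, *parts) -> int:
    """Stable sub-seed from the master seed and a stage/group/replicate path."""
    token = ":".join([str(master_seed), *map(str, parts)])
    digest = hashlib.sha256(token.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class StudyConfig:
    """Design of one synthetic study run."""

    ages: Sequence[int] = (2, 4, 8, 12, 16, 20)
    genotypes: Sequence[str] = ("WT", "SOD1")
    n_nmjs_per_group: int = 10
    n_images_per_group: int = 10
    master_seed: int = 1
    output_dir: str = "study_out"
    include_trains: bool = False
    image_ages: Optional[Sequence[int]] = None   # default: ages >= 4
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_nmjs_per_group <= 0 or self.n_images_per_group < 0:
            raise ValueError("group counts must be positive")


def simulate_ephys_group(age: int, genotype: str, n_nmjs: int, master_seed: int,
                         include_train: bool = False) -> pd.DataFrame:
    """Simulate and analyze ``n_nmjs`` NMJs of one group; returns summary rows."""
    scenario = build_scenario(age, genotype)
    rows = []
    for k in range(n_nmjs):
        s_spont = derive_seed(master_seed, "ephys", genotype, age, k, "spont")
        s_evoked = derive_seed(master_seed, "ephys", genotype, age, k, "evoked")
        sp_protocol = spontaneous_protocol()
        trace_sp, _ = simulate_recording(scenario, sp_protocol, s_spont)
        trace_ev, _ = simulate_recording(scenario, evoked_protocol(), s_evoked)
        mepps = detect_mepps(trace_sp)
        epps = measure_epps(trace_ev)
        train_amps = None
        if include_train:
            s_train = derive_seed(master_seed, "ephys", genotype, age, k, "train")
            trace_tr, _ = simulate_train(scenario, s_train)
            train_amps = measure_train(trace_tr).amplitude
        summary = summarize_nmj(mepps, epps, sp_protocol.duration, train_amps)
        row = {"unit_id": f"{genotype}-{age}w-nmj{k:03d}", "age_weeks": age,
               "genotype": genotype, **summary.to_dict()}
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> dict:
    """Run the full synthetic study and write the report bundle.

    Stages: per-group electrophysiology (simulate + detect + summarize),
    per-group imaging (generate + morphometry), then group statistics.  A
    ``manifest.json`` records the configuration, seeds, package version and
    per-stage timing; any stage failure halts the run with intermediates
    preserved on disk.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timing = {}

    t0 = time.perf_counter()
    ephys_frames = []
    for genotype in config.genotypes:
        for age in config.ages:
            ephys_frames.append(simulate_ephys_group(
                age, genotype, config.n_nmjs_per_group, config.master_seed,
                include_train=config.include_trains))
    ephys = pd.concat(ephys_frames, ignore_index=True)
    ephys.to_csv(outdir / "ephys_per_nmj.csv", index=False)
    timing["ephys_s"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    image_ages = config.image_ages
    if image_ages is None:
        image_ages = [a for a in config.ages if a >= 4]
    morpho_rows, manifest_rows = [], []
    for genotype in config.genotypes:
        for age in image_ages:
            scenario = build_image_scenario(age, genotype)
            for k in range(config.n_images_per_group):
                seed = derive_seed(config.master_seed, "image", genotype, age, k)
                image, truth = generate_nmj(scenario, seed)
                record = analyze_image(image)
                morpho_rows.append({"unit_id": f"{genotype}-{age}w-img{k:03d}",
                                    "age_weeks": age, "genotype": genotype,
                                    **record.to_dict()})
                manifest_rows.append({"unit_id": f"{genotype}-{age}w-img{k:03d}",
                                      **truth_manifest_row(image, truth)})
    morpho = pd.DataFrame(morpho_rows)
    if len(morpho):
        morpho.to_csv(outdir / "morphometry_per_nmj.csv", index=False)
        pd.DataFrame(manifest_rows).to_csv(outdir / "image_manifest.csv", index=False)
    timing["imaging_s"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    tables = build_report(ephys, morpho if len(morpho) else None, outdir / "report")
    timing["stats_s"] = round(time.perf_counter() - t0, 3)

    manifest = {
        "nmjkit_version": __version__,
        "master_seed": config.master_seed,
        "ages": list(config.ages),
        "genotypes": list(config.genotypes),
        "n_nmjs_per_group": config.n_nmjs_per_group,
        "n_images_per_group": config.n_images_per_group,
        "include_trains": config.include_trains,
        "timing": timing,
        "outputs": sorted(str(p.relative_to(outdir)) for p in outdir.rglob("*.csv")),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"ephys": ephys, "morpho": morpho, "report": tables, "manifest": manifest}
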