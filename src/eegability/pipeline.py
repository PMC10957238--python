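"""Orchestration: simulate → preprocess → decode → rdm → rsa → report.

Each stage derives its random stream from the top-level seed and a stage
label, writes its artifacts under the configured output directory, and
records a manifest entry (wall time, artifact checksums). Re-running the
same configuration reproduces the checksums of deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import child_seed
from .cohort import simulate_cohort
from .config import RunConfig
from .datasets import CohortDataset
from .decoding import ability_decoding_timecourse, timecourse_group_decoding
from .geometry import GeometrySpec, make_latent_geometries
from .io import export_tables, read_cohort, write_cohort
from .models import simulate_embeddings, simulate_model_activations
from .preprocessing import match_trial_counts, preprocess_cohort
from .rdm import activation_rdm, brain_rdm_timecourse, embedding_rdm
from .rsa_stats import compare_groups_rsa
from .stimuli import make_stimulus_set

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "preprocess", "decode", "rdm", "rsa", "report")


def _checksum(path: Path) -> str:
    """Content checksum; HDF5 files are hashed logically (dataset names +
    payload bytes) so the hash is independent of container metadata."""
    h = hashlib.sha256()
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            names: list[str] = []
            f.visit(names.append)
            for name in sorted(names):
                obj = f[name]
                h.update(name.encode())
                if isinstance(obj, h5py.Dataset):
                    vals = obj[()]
                    if vals.dtype == object:  # variable-length strings
                        for v in np.ravel(vals):
                            h.update(v if isinstance(v, bytes) else str(v).encode())
                    else:
                        h.update(np.ascontiguousarray(vals).tobytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _timecourse_csv(path: Path, tc) -> None:
    df = pd.DataFrame({"time_ms": tc.times_ms, "value": tc.values})
    if tc.p_values is not None:
        df["p"] = tc.p_values
    df.to_csv(path, index=False)


def run_pipeline(
    config: RunConfig, stages: tuple[str, ...] = STAGES, out_dir: str | None = None
) -> dict:
    """Execute the requested stages in order and return the run manifest.

    Later stages read the artifacts of earlier ones from the output
    directory, so stages can be re-run independently.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config": config.model_dump(mode="json"),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    artifacts: dict[str, Path] = {}

    def record(stage: str, t0: float, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "artifacts": {f.name: _checksum(f) for f in files},
        }
        for f in files:
            artifacts[f.name] = f

    cc = config.cohort
    stimuli = make_stimulus_set(
        cc.n_face, cc.n_nonface, n_identities=cc.n_identities,
        seed=child_seed(config.seed, "stimuli"),
    )
    specs = [GeometrySpec(**g.model_dump()) for g in cc.geometries]
    geometries = make_latent_geometries(
        stimuli,
        specs,
        seed=child_seed(config.seed, "geometries"),
        max_pairwise_spearman=cc.geometry_correlation_bound,
    )

    cohort: CohortDataset | None = None
    cohort_path = out / "cohort.h5"
    pre_path = out / "cohort_preprocessed.h5"

    if "simulate" in stages:
        t0 = time.perf_counter()
        cohort = simulate_cohort(
            stimuli,
            geometries,
            n_super=cc.n_super,
            n_typical=cc.n_typical,
            n_trials_per_participant=cc.n_trials_per_participant,
            n_channels=cc.n_channels,
            sampling_rate=cc.sampling_rate,
            epoch_window_ms=cc.epoch_window_ms,
            noise_sd=cc.noise_sd,
            jitter_sd=cc.jitter_sd,
            evoked_strength=cc.evoked_strength,
            noise_smoothing_ms=cc.noise_smoothing_ms,
            p_repeat=cc.p_repeat,
            n_sessions=cc.n_sessions,
            hit_rate=cc.hit_rate,
            metadata_only=cc.metadata_only,
            seed=child_seed(config.seed, "cohort"),
        )
        write_cohort(cohort_path, cohort)
        tables = export_tables(cohort, out / "tables")
        record("simulate", t0, [cohort_path, *tables])

    def _load(path: Path) -> CohortDataset:
        if not path.exists():
            raise FileNotFoundError(f"missing upstream artifact: {path}")
        return read_cohort(path)

    if "preprocess" in stages:
        t0 = time.perf_counter()
        cohort = cohort if cohort is not None else _load(cohort_path)
        if cohort.meta.get("metadata_only"):
            raise ValueError("cannot preprocess a metadata-only cohort")
        pc = config.preprocessing
        pre = preprocess_cohort(
            cohort,
            reference_channel=pc.reference_channel,
            band=pc.band,
            epoch_window_ms=pc.epoch_window_ms,
            target_rate=pc.target_rate,
            baseline_window_ms=pc.baseline_window_ms,
        )
        if pc.match_trials:
            pre = match_trial_counts(pre, seed=child_seed(config.seed, "trial-matching"))
        write_cohort(pre_path, pre)
        cohort = pre
        record("preprocess", t0, [pre_path])

    def _analysis_cohort() -> CohortDataset:
        nonlocal cohort
        if cohort is None:
            cohort = _load(pre_path if pre_path.exists() else cohort_path)
        return cohort

    if "decode" in stages:
        t0 = time.perf_counter()
        co = _analysis_cohort()
        dc = config.decoding
        files = []
        group_tc = timecourse_group_decoding(
            co,
            dc.condition,
            n_folds=dc.n_folds,
            n_repetitions=dc.n_repetitions,
            n_permutations=dc.n_permutations,
            grouped_cv=dc.grouped_cv,
            seed=child_seed(config.seed, "decode/group"),
        )
        p = out / "group_decoding.csv"
        _timecourse_csv(p, group_tc)
        files.append(p)
        typicals = [
            pid
            for pid in co.participant_ids
            if co.group_of(pid) == "typical" and pid in co.epochs
        ]
        if dc.run_ability and len(typicals) >= 3:
            ability_tc = ability_decoding_timecourse(
                co.subset(typicals),
                fractions=None if dc.fractions is None else np.asarray(dc.fractions),
                split=dc.ability_split,
                n_repetitions=dc.ability_repetitions,
                n_permutations=dc.ability_permutations,
                seed=child_seed(config.seed, "decode/ability"),
            )
            p = out / "ability_decoding.csv"
            _timecourse_csv(p, ability_tc)
            files.append(p)
        record("decode", t0, files)

    rdm_path = out / "brain_rdms.h5"
    if "rdm" in stages:
        t0 = time.perf_counter()
        co = _analysis_cohort()
        rc = config.rsa
        import h5py

        with h5py.File(rdm_path, "w") as f:
            for pid, es in co.epochs.items():
                tc = brain_rdm_timecourse(
                    es,
                    n_folds=rc.rdm_folds,
                    n_repetitions=rc.rdm_repetitions,
                    seed=child_seed(config.seed, f"rdm/{pid}"),
                )
                g = f.create_group(pid)
                g.create_dataset("rdm", data=tc.data, compression="gzip", compression_opts=1)
                g.create_dataset("stimulus_ids", data=tc.stimulus_ids)
                if "time_ms" not in f:
                    f.create_dataset("time_ms", data=tc.times_ms)
        record("rdm", t0, [rdm_path])

    if "rsa" in stages:
        t0 = time.perf_counter()
        co = _analysis_cohort()
        rc = config.rsa
        import h5py

        from .rdm import RDMTimecourse

        if not rdm_path.exists():
            raise FileNotFoundError(f"missing upstream artifact: {rdm_path}")
        tcs: dict[str, RDMTimecourse] = {}
        with h5py.File(rdm_path, "r") as f:
            times = f["time_ms"][()]
            for pid in f:
                if pid == "time_ms":
                    continue
                tcs[pid] = RDMTimecourse(
                    f[pid]["rdm"][()], times, "cv_auc", f[pid]["stimulus_ids"][()]
                )
        groups = {pid: co.group_of(pid) for pid in tcs}

        model_rdms = {}
        for geom in geometries:
            if geom.name == "semantic":
                emb = simulate_embeddings(
                    geom.target_rdm, seed=child_seed(config.seed, "rsa/emb")
                )
                model_rdms[geom.name] = embedding_rdm(emb, stimuli.ids)
            else:
                acts = simulate_model_activations(
                    geom.target_rdm, seed=child_seed(config.seed, f"rsa/{geom.name}")
                )
                model_rdms[geom.name] = activation_rdm(acts, stimuli.ids)

        names = list(model_rdms)
        report = {}
        both_groups = len(set(groups.values())) == 2
        for i, name in enumerate(names):
            conditioning = model_rdms[names[1 - i]] if len(names) == 2 else None
            if both_groups:
                _, cluster = compare_groups_rsa(
                    tcs,
                    groups,
                    model_rdms[name],
                    conditioning,
                    t_threshold=rc.t_threshold,
                    alpha=rc.alpha,
                    n_permutations=rc.n_permutations,
                    seed=child_seed(config.seed, f"rsa/cluster/{name}"),
                )
                report[name] = {
                    "conditioning": names[1 - i] if conditioning is not None else None,
                    "clusters": [
                        dict(
                            start_ms=c.start_ms,
                            end_ms=c.end_ms,
                            sign=c.sign,
                            size=c.size,
                            p_value=c.p_value,
                            significant=c.p_value < rc.alpha,
                        )
                        for c in cluster.clusters
                    ],
                }
        p = out / "rsa_clusters.json"
        p.write_text(json.dumps(report, indent=2))
        record("rsa", t0, [p])

    if "report" in stages:
        t0 = time.perf_counter()
        summary = {
            "stages_run": [s for s in stages if s in manifest["stages"] or s == "report"],
            "artifacts": sorted(a for a in artifacts),
        }
        p = out / "summary.json"
        p.write_text(json.dumps(summary, indent=2))
        record("report", t0, [p])

    manifest["versions"] = _versions()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _versions() -> dict:
    import scipy
    import sklearn

    from . import __version__

    return {
        "eegability": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "pandas": pd.__version__,
    }
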