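"""Plain-text file formats: manifest datasets, truth files, fit results.

Everything is TSV (node counts stay small, so files remain diff-able).
A dataset directory holds ``manifest.tsv`` (participant_id, path, T), one
time-series TSV per participant (header row of node labels, one row per
time point) and, for simulated data, a ``truth/`` subdirectory.  All node
and edge identifiers are 1-based on disk.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluate import inclusion_bf
from .ggm import ParticipantData, prepare_data
from .netcore import edge_table
from .simulate import SimulationTruth

__all__ = [
    "ManifestError",
    "write_dataset",
    "read_manifest",
    "read_dataset",
    "write_fit_result",
    "read_fit_dir",
    "read_truth_dir",
]


class ManifestError(ValueError):
    """Raised for malformed manifests or inconsistent series files."""


# --------------------------------------------------------------------------
# datasets
# --------------------------------------------------------------------------


def write_dataset(truth: SimulationTruth, outdir: str | Path) -> Path:
    """Write a simulated study as a manifest dataset plus truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels = [f"node{p + 1}" for p in range(truth.space.P)]
    rows = []
    for n, series in enumerate(truth.timeseries):
        pid = f"sub-{n + 1:03d}"
        fname = f"{pid}.tsv"
        pd.DataFrame(series, columns=labels).to_csv(
            outdir / fname, sep="\t", index=False, float_format="%.10g"
        )
        rows.append({"participant_id": pid, "path": fname, "T": series.shape[0]})
    pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)

    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    base = edge_table(truth.space)
    base.assign(present=truth.group_graph).to_csv(
        tdir / "group_edges.tsv", sep="\t", index=False
    )
    base.assign(mu=truth.mu).to_csv(
        tdir / "mu.tsv", sep="\t", index=False, float_format="%.10g"
    )
    (tdir / "sigma.txt").write_text(f"{truth.sigma}\n")
    ind = pd.DataFrame(
        truth.individual_graphs,
        columns=[f"edge_{e + 1}" for e in range(truth.space.E)],
    )
    ind.insert(0, "participant_id", [r["participant_id"] for r in rows])
    ind.to_csv(tdir / "individual_edges.tsv", sep="\t", index=False)
    if truth.labels is not None:
        pd.DataFrame(
            {
                "participant_id": [r["participant_id"] for r in rows],
                "group": truth.labels,
            }
        ).to_csv(tdir / "labels.tsv", sep="\t", index=False)
    if truth.group_graph_2 is not None:
        base.assign(present=truth.group_graph_2).to_csv(
            tdir / "group_edges_2.tsv", sep="\t", index=False
        )
    return outdir


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    manifest = pd.read_csv(path, sep="\t")
    required = {"participant_id", "path", "T"}
    if not required.issubset(manifest.columns):
        raise ManifestError(
            f"manifest {path} must have columns {sorted(required)}"
        )
    if manifest["participant_id"].duplicated().any():
        dup = manifest["participant_id"][manifest["participant_id"].duplicated()]
        raise ManifestError(f"duplicate participant ids in {path}: {list(dup)}")
    return manifest


def read_dataset(
    manifest_path: str | Path, standardize: bool = True
) -> tuple[list[ParticipantData], list[str]]:
    """Load every participant listed in a manifest, in manifest order.

    Validates that all series share one node-label header and that row
    counts match the manifest; errors name the offending file (and line
    where possible).  Returns ``(participants, participant_ids)``.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    root = manifest_path.parent
    participants: list[ParticipantData] = []
    header: list[str] | None = None
    header_file = None
    for row in manifest.itertuples(index=False):
        fpath = root / row.path
        if not fpath.exists():
            raise ManifestError(f"series file missing: {fpath}")
        try:
            frame = pd.read_csv(fpath, sep="\t")
        except Exception as err:
            raise ManifestError(f"cannot parse {fpath}: {err}") from err
        cols = list(frame.columns)
        if header is None:
            header, header_file = cols, fpath
        elif cols != header:
            raise ManifestError(
                f"node-label header of {fpath} differs from {header_file}"
            )
        values = frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = frame.map(
                lambda v: not isinstance(v, (int, float, np.number))
            )
            line = int(bad.any(axis=1).idxmax()) + 2  # header + 1-based
            raise ManifestError(f"non-numeric cell in {fpath} near line {line}")
        if values.shape[0] != row.T:
            raise ManifestError(
                f"{fpath}: manifest says T={row.T}, file has {values.shape[0]} rows"
            )
        participants.append(prepare_data(values, standardize=standardize, labels=cols))
    return participants, list(manifest["participant_id"])


def read_truth_dir(truth_dir: str | Path) -> dict:
    """Load the truth files of a simulated dataset into arrays."""
    tdir = Path(truth_dir)
    group = pd.read_csv(tdir / "group_edges.tsv", sep="\t")
    out = {
        "group_graph": group["present"].to_numpy(np.uint8),
        "mu": pd.read_csv(tdir / "mu.tsv", sep="\t")["mu"].to_numpy(),
        "sigma": float((tdir / "sigma.txt").read_text().strip()),
    }
    ind = pd.read_csv(tdir / "individual_edges.tsv", sep="\t")
    out["individual_graphs"] = ind.drop(columns="participant_id").to_numpy(np.uint8)
    labels = tdir / "labels.tsv"
    if labels.exists():
        out["labels"] = pd.read_csv(labels, sep="\t")["group"].to_numpy()
    return out


# --------------------------------------------------------------------------
# fit results
# --------------------------------------------------------------------------


def write_fit_result(
    result, outdir: str | Path, participant_ids: list[str] | None = None
) -> Path:
    """Serialize a FitResult as a directory of TSVs plus a run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    space = result.store.space
    base = edge_table(space)

    bf = np.array(
        [
            inclusion_bf(min(max(p, 1e-12), 1 - 1e-12), 0.5)
            for p in result.group_probs
        ]
    )
    group = base.assign(
        mu_mean=result.mu_mean if result.mu_mean is not None else np.nan,
        mu_sd=result.mu_sd if result.mu_sd is not None else np.nan,
        incl_prob=result.group_probs,
        bf=bf,
    )
    group.to_csv(outdir / "group.tsv", sep="\t", index=False, float_format="%.10g")
    if result.sigma_mean is not None:
        (outdir / "sigma.tsv").write_text(
            "sigma_mean\tsigma_sd\n"
            f"{result.sigma_mean:.10g}\t{result.sigma_sd:.10g}\n"
        )

    N = result.n_participants
    ids = participant_ids or [f"sub-{n + 1:03d}" for n in range(N)]
    idir = outdir / "individual"
    idir.mkdir(exist_ok=True)
    for n, pid in enumerate(ids):
        base.assign(
            incl_prob=result.individual_probs[n],
            pcor_mean=result.pcor_means[n],
        ).to_csv(idir / f"{pid}.tsv", sep="\t", index=False, float_format="%.10g")

    if result.rhat_mu is not None:
        base.assign(rhat_mu=result.rhat_mu).to_csv(
            outdir / "rhat.tsv", sep="\t", index=False, float_format="%.6g"
        )

    cfg = result.config
    resolved = {
        "method": cfg.method,
        "iterations": cfg.iterations,
        "burnin": cfg.burnin,
        "chains": cfg.chains,
        "seed": cfg.seed,
        "thin": cfg.thin,
        "standardize": cfg.standardize,
        "parallel_workers": cfg.parallel_workers,
        "v0": cfg.hyper.v0,
        "v1": cfg.hyper.v1,
        "lambda": cfg.hyper.lam,
        "mu_prior_sd": cfg.prior.mu_prior_sd,
        "sigma_prior_scale": cfg.prior.sigma_prior_scale,
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))

    lines = [f"method: {cfg.method}", f"seed: {cfg.seed}"]
    for entry in result.log.get("acceptance", []):
        if entry:
            lines.append(
                f"acceptance mu={entry['mu']:.3f} sigma={entry['sigma']:.3f}"
            )
    if result.rhat_sigma is not None and result.rhat_mu is not None:
        lines.append(
            f"rhat: sigma={result.rhat_sigma:.4f} "
            f"mu_max={np.max(result.rhat_mu):.4f}"
        )
    (outdir / "run.log").write_text("\n".join(lines) + "\n")
    return outdir


def read_fit_dir(outdir: str | Path) -> dict:
    """Load the tables written by :func:`write_fit_result`."""
    outdir = Path(outdir)
    group = pd.read_csv(outdir / "group.tsv", sep="\t")
    idir = outdir / "individual"
    files = sorted(idir.glob("*.tsv"))
    probs = []
    pcors = []
    ids = []
    for f in files:
        tab = pd.read_csv(f, sep="\t")
        probs.append(tab["incl_prob"].to_numpy())
        pcors.append(tab["pcor_mean"].to_numpy())
        ids.append(f.stem)
    return {
        "group_probs": group["incl_prob"].to_numpy(),
        "group_bf": group["bf"].to_numpy(),
        "individual_probs": np.vstack(probs),
        "pcor_means": np.vstack(pcors),
        "participant_ids": ids,
        "config": yaml.safe_load((outdir / "config.yaml").read_text()),
    }
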