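"""Readers and writers for the plain-text pipeline formats.

Data files are deliberately simple text formats so that runs round-trip and
diff cleanly:

* candidate matrix — CSV, cells x dims, index column of cell IDs, header
  PC1..PCn;
* cell metadata — TSV with columns cell_id, subject_id, init_cluster;
* abundant parameters — CSV, one row per (cluster, dim) with mean and
  variance columns, or computed from abundant cells + labels;
* chain summary — a directory of TSV/CSV files plus a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .em import AbundantClusterParams
from .gibbs import Chain, MultiSubjectMatrix

__all__ = [
    "read_candidate_data",
    "write_candidate_data",
    "read_abundant_params",
    "write_abundant_params",
    "abundant_from_cell_table",
    "write_fit_outputs",
    "read_chain_summary",
    "load_config",
    "write_manifest",
]


def read_candidate_data(matrix_path, metadata_path):
    """Load candidate cells and their initial labels.

    Returns ``(MultiSubjectMatrix, init_labels)``; metadata rows are
    matched to matrix rows by cell_id and must cover them exactly.
    """
    mat = pd.read_csv(matrix_path, index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    for col in ("cell_id", "subject_id", "init_cluster"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    meta = meta.set_index("cell_id")
    missing = mat.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"metadata missing {len(missing)} cell(s), "
                         f"e.g. {missing[0]!r}")
    meta = meta.loc[mat.index]
    subj_codes, subj_ids = pd.factorize(meta["subject_id"])
    data = MultiSubjectMatrix(
        mat.to_numpy(dtype=float), subj_codes,
        [str(s) for s in subj_ids], [str(c) for c in mat.index],
    )
    labels = np.asarray(meta["init_cluster"], dtype=int)
    return data, labels


def write_candidate_data(outdir, data: MultiSubjectMatrix, init_labels) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [f"PC{j + 1}" for j in range(data.G)]
    pd.DataFrame(data.X, index=pd.Index(data.cell_ids, name="cell_id"),
                 columns=cols).to_csv(outdir / "candidates.csv")
    pd.DataFrame({
        "cell_id": data.cell_ids,
        "subject_id": [data.subject_ids[d] for d in data.subject],
        "init_cluster": np.asarray(init_labels, dtype=int),
    }).to_csv(outdir / "candidates_meta.tsv", sep="\t", index=False)


def read_abundant_params(path) -> AbundantClusterParams:
    """Read the long-format abundant-parameter CSV (cluster, dim, mean, variance)."""
    df = pd.read_csv(path)
    for col in ("cluster", "dim", "mean", "variance"):
        if col not in df.columns:
            raise ValueError(f"abundant params file missing column {col!r}")
    names = list(pd.unique(df["cluster"]))
    wide_m = df.pivot(index="dim", columns="cluster", values="mean")
    wide_v = df.pivot(index="dim", columns="cluster", values="variance")
    wide_m = wide_m.sort_index()[names]
    wide_v = wide_v.sort_index()[names]
    return AbundantClusterParams(wide_m.to_numpy(), wide_v.to_numpy(),
                                 [str(n) for n in names])


def write_abundant_params(path, params: AbundantClusterParams) -> None:
    rows = []
    for k, name in enumerate(params.names):
        for g in range(params.G):
            rows.append({"cluster": name, "dim": g,
                         "mean": params.means[g, k],
                         "variance": params.variances[g, k]})
    pd.DataFrame(rows).to_csv(path, index=False)


def abundant_from_cell_table(matrix_path, labels_path) -> AbundantClusterParams:
    """Abundant parameters from abundant cells (CSV) + labels TSV (cell_id, cluster_id)."""
    mat = pd.read_csv(matrix_path, index_col=0)
    lab = pd.read_csv(labels_path, sep="\t")
    if not {"cell_id", "cluster_id"} <= set(lab.columns):
        raise ValueError("labels file needs columns cell_id, cluster_id")
    lab = lab.set_index("cell_id").loc[mat.index, "cluster_id"]
    return AbundantClusterParams.from_cells(mat.to_numpy(dtype=float),
                                            lab.to_numpy())


def write_manifest(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def write_fit_outputs(outdir, results, manifest: dict | None = None) -> None:
    """Persist a fitted model: cluster calls, summaries, draws, cell labels."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results.cluster_table().to_csv(outdir / "clusters.tsv", sep="\t", index=False)

    chain = results.chain
    data = results.model.data
    pi_mean = results.posterior_mean_pi
    rows = [{"subject_id": data.subject_ids[d], "cluster": k,
             "pi_mean": pi_mean[d, k]}
            for d in range(data.D) for k in range(chain.K)]
    pd.DataFrame(rows).to_csv(outdir / "pi_mean.tsv", sep="\t", index=False)

    for name, arr in (("mu_mean", results.posterior_mean_mu),
                      ("sigma2_mean", results.posterior_mean_sigma2)):
        rows = [{"dim": g, "cluster": k, "value": arr[g, k]}
                for g in range(arr.shape[0]) for k in range(arr.shape[1])]
        pd.DataFrame(rows).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)

    # per-iteration pi draws, needed by standalone group inference
    S, D, K = chain.pi.shape
    draws = pd.DataFrame({
        "iter": np.repeat(np.arange(S), D * K),
        "subject_id": np.tile(np.repeat(np.asarray(data.subject_ids), K), S),
        "cluster": np.tile(np.arange(K), S * D),
        "value": chain.pi.reshape(-1),
    })
    draws.to_csv(outdir / "pi_draws.csv", index=False)

    results.cell_table().to_csv(outdir / "cell_labels.tsv", sep="\t", index=False)
    if manifest is not None:
        write_manifest(outdir / "manifest.json", manifest)


def read_chain_summary(outdir):
    """Reload the pieces of a saved fit needed for standalone inference.

    Returns ``(cluster_table, pi_mean wide DataFrame, pi draws (S, D, K)
    array, subject_ids)``.
    """
    outdir = Path(outdir)
    clusters = pd.read_csv(outdir / "clusters.tsv", sep="\t")
    pi_mean = pd.read_csv(outdir / "pi_mean.tsv", sep="\t").pivot(
        index="subject_id", columns="cluster", values="pi_mean")
    draws = pd.read_csv(outdir / "pi_draws.csv")
    subject_ids = list(pd.unique(draws["subject_id"]))
    S = int(draws["iter"].max()) + 1
    K = int(draws["cluster"].max()) + 1
    arr = np.empty((S, len(subject_ids), K))
    code = {s: j for j, s in enumerate(subject_ids)}
    arr[draws["iter"].to_numpy(),
        draws["subject_id"].map(code).to_numpy(),
        draws["cluster"].to_numpy()] = draws["value"].to_numpy()
    pi_mean = pi_mean.loc[subject_ids]
    return clusters, pi_mean, arr, subject_ids


def load_config(path) -> dict:
    """Load a YAML or JSON run-configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}
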