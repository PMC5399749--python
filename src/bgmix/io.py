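"""Tab-separated file I/O: labelled matrices, model parameter tables,
assignments, responsibilities, reports and traces.

Matrix files are TSV with a header row of variable names and a first column
of entity labels.  When both a binary and a continuous matrix are loaded
they are row-aligned by entity label, with the binary file's order
governing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import ComponentParams, HardClustering, MixedDataset, MixtureModel
from .preprocess import binarize_binding, normalize_expression

__all__ = [
    "read_matrix",
    "write_matrix",
    "load_mixed_dataset",
    "write_model",
    "read_model",
    "write_assignments",
    "write_responsibilities",
]


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}"
        )
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def load_mixed_dataset(
    binary_path: str | Path | None = None,
    continuous_path: str | Path | None = None,
    binarize_pvalues: bool = False,
    binding_threshold: float = 0.001,
    normalize: bool = False,
) -> MixedDataset:
    """Load aligned binary and continuous matrices (either may be omitted).

    With ``binarize_pvalues`` the binary file is read as binding p-values
    and thresholded at ``binding_threshold``; with ``normalize`` each
    continuous row is z-scored.
    """
    if binary_path is None and continuous_path is None:
        raise ValueError("at least one of the two matrices is required")
    bdf = read_matrix(binary_path) if binary_path is not None else None
    cdf = read_matrix(continuous_path) if continuous_path is not None else None
    if bdf is not None and cdf is not None:
        if set(bdf.index) != set(cdf.index):
            only_b = sorted(set(bdf.index) - set(cdf.index))[:3]
            only_c = sorted(set(cdf.index) - set(bdf.index))[:3]
            raise ValueError(
                f"entity labels differ between files "
                f"(only in binary: {only_b}; only in continuous: {only_c})"
            )
        cdf = cdf.loc[bdf.index]  # binary file order governs
    ids = list((bdf if bdf is not None else cdf).index.astype(str))
    if bdf is not None:
        R = bdf.to_numpy(dtype=float)
        if binarize_pvalues:
            R = binarize_binding(R, binding_threshold)
        else:
            bad = np.argwhere(~np.isin(R, (0.0, 1.0)))
            if bad.size:
                i, j = bad[0]
                raise ValueError(
                    f"{binary_path}: non-binary entry {R[i, j]!r} at row "
                    f"{bdf.index[i]!r}, column {bdf.columns[j]!r}"
                )
        binary_names = list(bdf.columns.astype(str))
    else:
        R = np.zeros((len(ids), 0))
        binary_names = []
    if cdf is not None:
        E = cdf.to_numpy(dtype=float)
        if normalize:
            E = normalize_expression(E, ids)
        continuous_names = list(cdf.columns.astype(str))
    else:
        E = np.zeros((len(ids), 0))
        continuous_names = []
    return MixedDataset(
        entity_ids=ids,
        binary_names=binary_names,
        continuous_names=continuous_names,
        R=R,
        E=E,
    )


def _model_frame(model: MixtureModel, binary_names: list[str],
                 continuous_names: list[str]) -> pd.DataFrame:
    rows = []
    for m, comp in enumerate(model.components, start=1):
        rows.append({"component": m, "variable": "_alpha", "type": "mixing",
                     "param1": comp.alpha, "param2": ""})
        for j, name in enumerate(binary_names):
            rows.append({"component": m, "variable": name, "type": "bernoulli",
                         "param1": comp.p[j], "param2": ""})
        for l, name in enumerate(continuous_names):
            rows.append({"component": m, "variable": name, "type": "gaussian",
                         "param1": comp.mu[l], "param2": comp.sigma[l]})
    return pd.DataFrame(rows, columns=["component", "variable", "type",
                                       "param1", "param2"])


def write_model(model: MixtureModel, binary_names: list[str],
                continuous_names: list[str], path: str | Path) -> None:
    """Write the parameter table: one row per component per variable plus a
    mixing-weight row per component."""
    _model_frame(model, binary_names, continuous_names).to_csv(
        path, sep="\t", index=False
    )


def read_model(path: str | Path) -> tuple[MixtureModel, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t")
    comps = []
    binary_names: list[str] = []
    continuous_names: list[str] = []
    for m, grp in df.groupby("component", sort=True):
        alpha = float(grp.loc[grp["type"] == "mixing", "param1"].iloc[0])
        bern = grp[grp["type"] == "bernoulli"]
        gaus = grp[grp["type"] == "gaussian"]
        if not binary_names:
            binary_names = list(bern["variable"].astype(str))
        if not continuous_names:
            continuous_names = list(gaus["variable"].astype(str))
        comps.append(
            ComponentParams(
                alpha=alpha,
                p=bern["param1"].to_numpy(dtype=float),
                mu=gaus["param1"].to_numpy(dtype=float),
                sigma=gaus["param2"].to_numpy(dtype=float),
            )
        )
    model = MixtureModel(
        components=comps, n_r=len(binary_names), n_e=len(continuous_names)
    )
    return model, binary_names, continuous_names


def write_assignments(clustering: HardClustering, entity_ids: list[str],
                      path: str | Path) -> None:
    pd.DataFrame(
        {"entity": entity_ids, "cluster": clustering.assignment + 1}
    ).to_csv(path, sep="\t", index=False)


def write_responsibilities(gamma: np.ndarray, entity_ids: list[str],
                           path: str | Path) -> None:
    df = pd.DataFrame(
        gamma,
        index=pd.Index(entity_ids, name="entity"),
        columns=[f"cluster_{m + 1}" for m in range(gamma.shape[1])],
    )
    df.to_csv(path, sep="\t")


def write_trace(trace, path: str | Path) -> None:
    pd.DataFrame(
        trace,
        columns=["temperature", "current_objective", "best_objective",
                 "n_clusters"],
    ).rename_axis("step").to_csv(path, sep="\t")
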