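"""File formats, run configuration, and the end-to-end pipeline.

All on-disk formats are plain text: delimited square matrices for networks
(``.csv`` comma, ``.tsv``/``.txt`` tab/whitespace), MATLAB-style ``.mat``
containers holding a ``q x q`` or ``q x q x m`` array, two-column diagram
exports, three-column Betti curves, and JSON test reports.  Node indexing is
1-based in file headers and 0-based internally.  Matrices are written at
full precision (``%.17g``) so a write/read round-trip is exact.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as sio

try:
    from importlib.metadata import version as _dist_version

    _pkg_version = _dist_version("topofilt")
except Exception:  # pragma: no cover - not installed
    _pkg_version = "unknown"

from .covariance import FeatureTable, jackknife_networks
from .distance import GroupedDistanceMatrix, pairwise_distances
from .exceptions import ConfigError, FormatError
from .inference import permutation_test, transposition_test, z_test
from .network import (
    BettiCurve,
    BirthDeathDecomposition,
    WeightedNetwork,
    betti_curves,
    birth_death_decompose,
)

__all__ = [
    "read_network",
    "read_networks",
    "write_network",
    "write_decomposition",
    "write_betti_curve",
    "write_distance_matrix",
    "write_report",
    "read_feature_table",
    "read_group_manifest",
    "RunConfig",
    "load_config",
    "run_pipeline",
]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


def _delimiter_for(path: Path) -> str | None:
    return "," if path.suffix.lower() == ".csv" else None


def _validate_matrix(a: np.ndarray, origin: str, tol: float = 1e-8) -> np.ndarray:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise FormatError(f"{origin}: matrix must be square, got shape {a.shape}")
    bad = np.argwhere(~np.isfinite(a))
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"{origin}: non-finite value at row {i + 1}, column {j + 1} (1-based)"
        )
    asym = np.abs(a - a.T).max() if a.size else 0.0
    if asym > tol:
        i, j = np.unravel_index(np.argmax(np.abs(a - a.T)), a.shape)
        raise FormatError(
            f"{origin}: asymmetry {asym:g} beyond tolerance {tol:g} "
            f"at row {i + 1}, column {j + 1} (1-based)"
        )
    if asym > 0:
        log.warning("%s: asymmetry %g within tolerance; symmetrized", origin, asym)
        a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


def read_network(path, labels_path=None, tol: float = 1e-8) -> WeightedNetwork:
    """Read one network from a delimited text matrix file."""
    path = Path(path)
    try:
        a = np.loadtxt(path, delimiter=_delimiter_for(path), ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: could not parse numeric matrix ({exc})") from exc
    a = _validate_matrix(a, str(path), tol)
    labels = None
    if labels_path is not None:
        labels = [line.strip() for line in Path(labels_path).read_text().splitlines() if line.strip()]
    return WeightedNetwork(a, node_labels=labels)


def _networks_from_mat(path: Path, tol: float) -> list[WeightedNetwork]:
    data = sio.loadmat(path)
    arrays = [
        v for k, v in data.items()
        if not k.startswith("__") and isinstance(v, np.ndarray) and v.ndim in (2, 3)
    ]
    if not arrays:
        raise FormatError(f"{path}: no q x q or q x q x m numeric array found")
    a = arrays[0].astype(float)
    if a.ndim == 2:
        return [WeightedNetwork(_validate_matrix(a, str(path), tol))]
    if a.shape[0] != a.shape[1]:
        raise FormatError(f"{path}: stacked array must be q x q x m, got {a.shape}")
    return [
        WeightedNetwork(_validate_matrix(a[:, :, k].copy(), f"{path}[:, :, {k}]", tol))
        for k in range(a.shape[2])
    ]


def read_networks(path, tol: float = 1e-8) -> tuple[list[WeightedNetwork], list[str]]:
    """Read networks from a file (text matrix or .mat stack) or a directory.

    Returns the networks plus string identifiers (file stem, with a
    ``#index`` suffix for stacked arrays).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".csv", ".tsv", ".txt", ".mat")
        )
        if not files:
            raise FormatError(f"{path}: no network files (.csv/.tsv/.txt/.mat) found")
        nets, names = [], []
        for p in files:
            sub, subnames = read_networks(p, tol)
            nets.extend(sub)
            names.extend(subnames)
        return nets, names
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.suffix.lower() == ".mat":
        nets = _networks_from_mat(path, tol)
        if len(nets) == 1:
            return nets, [path.stem]
        return nets, [f"{path.stem}#{k + 1}" for k in range(len(nets))]
    return [read_network(path, tol=tol)], [path.stem]


def write_network(net: WeightedNetwork, path) -> None:
    path = Path(path)
    delim = _delimiter_for(path) or "\t"
    np.savetxt(path, net.weights, fmt=_FLOAT_FMT, delimiter=delim)


def write_decomposition(bd: BirthDeathDecomposition, births_path, deaths_path) -> None:
    """Two-column (1-based index, value) exports of the sorted birth/death sets."""
    for values, path in ((bd.births, births_path), (bd.deaths, deaths_path)):
        idx = np.arange(1, len(values) + 1)
        np.savetxt(
            Path(path),
            np.column_stack([idx, values]) if len(values) else np.empty((0, 2)),
            fmt=("%d", _FLOAT_FMT),
            delimiter="\t",
            header="index\tvalue",
        )


def write_betti_curve(curve: BettiCurve, path) -> None:
    np.savetxt(
        Path(path),
        np.column_stack([curve.thresholds, curve.beta0, curve.beta1]),
        fmt=(_FLOAT_FMT, "%d", "%d"),
        delimiter="\t",
        header="epsilon\tbeta0\tbeta1",
    )


def write_distance_matrix(D: np.ndarray, path, header: str = "") -> None:
    np.savetxt(Path(path), np.asarray(D), fmt=_FLOAT_FMT, delimiter="\t", header=header)


def write_grouped_distances(gdm: GroupedDistanceMatrix, out_dir, stem: str = "dist") -> list[Path]:
    out_dir = Path(out_dir)
    header = f"groups: m={gdm.m} n={gdm.n}; order: first m rows group 1, next n group 2"
    paths = []
    for name, mat in (("D0", gdm.D0), ("D1", gdm.D1), ("D01", gdm.D01)):
        p = out_dir / f"{stem}_{name}.tsv"
        write_distance_matrix(mat, p, header=f"{name}; {header}")
        paths.append(p)
    labels_path = out_dir / f"{stem}_labels.txt"
    labels_path.write_text("".join(f"{lab + 1}\n" for lab in gdm.labels))
    paths.append(labels_path)
    return paths


def write_report(report, path, extra: dict | None = None) -> None:
    payload = report.summary()
    if extra:
        payload = {**payload, **extra}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_feature_table(path) -> FeatureTable:
    """Delimited table: header row of node ids, first column subject ids."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="," if path.suffix.lower() == ".csv" else r"\s+",
            index_col=0,
            float_precision="round_trip",
        )
    except Exception as exc:
        raise FormatError(f"{path}: could not parse feature table ({exc})") from exc
    if df.isna().any().any():
        cell = np.argwhere(df.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at subject {df.index[cell[0]]!r}, node {df.columns[cell[1]]!r}"
        )
    return FeatureTable.from_dataframe(df)


def write_feature_table(table: FeatureTable, path) -> None:
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    table.to_dataframe().to_csv(path, sep=sep, float_format="%.17g")


def read_group_manifest(path) -> dict[str, str]:
    """Two-column manifest: identifier, group label."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"manifest {path} does not exist")
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'identifier group', got {line!r}")
        mapping[parts[0]] = parts[1]
    groups = sorted(set(mapping.values()))
    if len(groups) != 2:
        raise FormatError(f"{path}: exactly two groups required, found {groups}")
    return mapping


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``feature_table`` (subject-by-node table, jackknifed into
    per-subject covariance networks) or ``networks`` (file/directory of
    weighted networks) must be given, together with a two-column group
    ``manifest``.
    """

    output_dir: str
    manifest: str
    feature_table: str | None = None
    networks: str | None = None
    method: str = "transposition"  # permutation | transposition | z
    n_resamples: int = 10_000
    full_perm_interval: int = 1000
    w0: float = 1.0
    w1: float = 1.0
    seed: int = 0
    grid_points: int = 100
    grid_mode: str = "linear"

    def validate(self) -> None:
        if (self.feature_table is None) == (self.networks is None):
            raise ConfigError("exactly one of feature_table or networks must be set")
        for name in ("feature_table", "networks", "manifest"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path {p!r} does not exist")
        if self.method not in ("permutation", "transposition", "z"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.n_resamples < 1:
            raise ConfigError("n_resamples must be >= 1")
        if self.w0 < 0 or self.w1 < 0:
            raise ConfigError("distance weights must be nonnegative")


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        cfg = RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return cfg


def _grouped_networks(config: RunConfig):
    """Resolve the two groups of networks named by the manifest."""
    mapping = read_group_manifest(config.manifest)
    groups = sorted(set(mapping.values()))
    if config.networks is not None:
        nets, names = read_networks(config.networks)
        missing = [n for n in names if n not in mapping]
        if missing:
            raise ConfigError(f"manifest missing entries for networks: {missing[:5]}")
        g1 = [net for net, n in zip(nets, names) if mapping[n] == groups[0]]
        g2 = [net for net, n in zip(nets, names) if mapping[n] == groups[1]]
        return g1, g2, groups
    table = read_feature_table(config.feature_table)
    missing = [s for s in table.subjects if s not in mapping]
    if missing:
        raise ConfigError(f"manifest missing entries for subjects: {missing[:5]}")
    out = []
    for g in groups:
        idx = [i for i, s in enumerate(table.subjects) if mapping[s] == g]
        sub = FeatureTable(
            tuple(table.subjects[i] for i in idx), table.node_ids, table.values[idx]
        )
        out.append(jackknife_networks(sub))
    return out[0], out[1], groups


def run_pipeline(config: RunConfig) -> dict:
    """Execute feature-table/networks -> decomposition -> distances -> inference.

    Writes per-network diagrams and Betti curves, the grouped distance
    matrices, the inference report, and a run log; returns a manifest of
    written paths plus the report object.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    stage = "load-inputs"
    artifacts: dict = {"output_dir": str(out)}
    timings: dict[str, float] = {}
    try:
        g1, g2, group_names = _grouped_networks(config)
        timings[stage] = time.perf_counter() - t0

        stage = "decompose"
        t = time.perf_counter()
        nets = g1 + g2
        decomps = [birth_death_decompose(net) for net in nets]
        diag_dir = out / "diagrams"
        diag_dir.mkdir(exist_ok=True)
        # one shared grid across all networks, derived from the pooled weights
        all_w = np.concatenate([net.edge_weights() for net in nets])
        lo, hi = float(all_w.min()), float(all_w.max())
        if config.grid_mode == "exact":
            grid = np.unique(all_w)
        else:
            delta = 1e-9 * (hi - lo) if hi > lo else 1e-3
            grid = np.linspace(lo - delta, hi, config.grid_points)
        for k, (net, bd) in enumerate(zip(nets, decomps), start=1):
            write_decomposition(
                bd, diag_dir / f"net{k:03d}_births.tsv", diag_dir / f"net{k:03d}_deaths.tsv"
            )
            write_betti_curve(
                betti_curves(net, grid, decomposition=bd), diag_dir / f"net{k:03d}_betti.tsv"
            )
        artifacts["diagrams"] = str(diag_dir)
        timings[stage] = time.perf_counter() - t

        stage = "distances"
        t = time.perf_counter()
        gdm = pairwise_distances(g1, g2, w0=config.w0, w1=config.w1)
        write_grouped_distances(gdm, out)
        artifacts["distances"] = str(out / "dist_D01.tsv")
        timings[stage] = time.perf_counter() - t

        stage = f"inference-{config.method}"
        t = time.perf_counter()
        if config.method == "permutation":
            report = permutation_test(gdm, n_perms=config.n_resamples, seed=config.seed)
        elif config.method == "transposition":
            report = transposition_test(
                gdm,
                n_transpositions=config.n_resamples,
                full_perm_interval=config.full_perm_interval,
                seed=config.seed,
            )
        else:
            report = z_test(gdm)
        report_path = out / f"report_{config.method}.json"
        write_report(
            report,
            report_path,
            extra={"groups": group_names, "m": gdm.m, "n": gdm.n, "seed": config.seed},
        )
        artifacts["report"] = str(report_path)
        artifacts["report_object"] = report
        timings[stage] = time.perf_counter() - t
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    log_path = out / "run.log"
    lines = [
        f"topofilt {_pkg_version}",
        f"numpy {np.__version__}",
        f"seed {config.seed}",
        f"method {config.method}",
        f"groups {group_names} sizes m={gdm.m} n={gdm.n}",
    ] + [f"stage {k}: {v:.3f} s" for k, v in timings.items()]
    log_path.write_text("".join(line + "\n" for line in lines))
    artifacts["log"] = str(log_path)
    for line in lines:
        log.info("%s", line)
    return artifacts
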