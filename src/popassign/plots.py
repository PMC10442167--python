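"""Figure builders for the result tables written by the CLI.

Purely presentational: every panel re-plots columns that already exist in
the CSV tables; no computation happens here beyond grouping.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_assignment_rates", "plot_rf_sweep", "plot_multiregion_map", "plot_binned_rates", "make_figures"]


def _check(table: pd.DataFrame, cols: list[str], what: str) -> None:
    if table.empty:
        raise ValueError(f"{what}: empty table, nothing to plot")
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"{what}: missing columns {missing}")


def plot_assignment_rates(table: pd.DataFrame, out: str | Path, fmt: str = "png") -> Path:
    """Simulated (solid) vs closed-form (dashed) error rate per N."""
    _check(table, ["N", "D_X", "rate", "theory_eq3"], "assignment rates")
    fig, ax = plt.subplots(figsize=(5, 4))
    for n, grp in table.groupby("N"):
        grp = grp.sort_values("D_X")
        noise = grp["D_X"] + grp["D_Y"]
        (line,) = ax.plot(noise, grp["rate"], "-o", label=f"N={n} (sim)")
        ax.plot(noise, grp["theory_eq3"], "--", color=line.get_color())
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"decoder variance $D_X + D_Y$")
    ax.set_ylabel("assignment error rate")
    ax.legend(fontsize=8)
    return _save(fig, out, fmt)


def plot_rf_sweep(table: pd.DataFrame, out: str | Path, fmt: str = "png") -> Path:
    """Theory (dashed) vs empirical (solid) MSE over the sweep variable."""
    _check(table, ["snr", "mse_theory"], "rf sweep")
    fig, ax = plt.subplots(figsize=(5, 4))
    for k, grp in table.groupby("K"):
        grp = grp.sort_values("snr")
        (line,) = ax.plot(grp["snr"], grp["mse_theory"], "--", label=f"K={k} theory")
        if "mse_empirical" in grp and grp["mse_empirical"].notna().any():
            ax.plot(grp["snr"], grp["mse_empirical"], "-o", color=line.get_color(), label=f"K={k} sim")
    ax.set_yscale("log")
    ax.set_xlabel("population SNR")
    ax.set_ylabel("total MSE per feature")
    ax.legend(fontsize=8)
    return _save(fig, out, fmt)


def plot_multiregion_map(argmin_map: pd.DataFrame, out: str | Path, fmt: str = "png") -> Path:
    """Best region count per (units, SNR) cell; 0 = excluded (white)."""
    if argmin_map.empty:
        raise ValueError("multiregion map: empty table")
    fig, ax = plt.subplots(figsize=(5, 4))
    data = argmin_map.to_numpy(dtype=float)
    masked = pd.DataFrame(data).where(lambda d: d > 0).to_numpy()
    im = ax.imshow(masked, origin="lower", aspect="auto", cmap="viridis", vmin=1, vmax=3)
    ax.set_xticks(range(len(argmin_map.columns)), [str(c) for c in argmin_map.columns])
    ax.set_yticks(range(len(argmin_map.index)), [str(i) for i in argmin_map.index])
    ax.set_xlabel("total population SNR")
    ax.set_ylabel("total units")
    fig.colorbar(im, label="regions minimizing total error")
    return _save(fig, out, fmt)


def plot_binned_rates(table: pd.DataFrame, out: str | Path, fmt: str = "png") -> Path:
    """Network assignment error rate vs common-feature distance, with theory."""
    _check(table, ["delta_bin_lo", "delta_bin_hi", "rate", "theory_F"], "binned rates")
    fig, ax = plt.subplots(figsize=(5, 4))
    centers = 0.5 * (table["delta_bin_lo"] + table["delta_bin_hi"])
    if "variant" in table.columns:
        for v, grp in table.groupby("variant"):
            c = 0.5 * (grp["delta_bin_lo"] + grp["delta_bin_hi"])
            ax.plot(c, grp["rate"], "-o", label=v)
        theory = table.drop_duplicates("delta_bin_lo")
        c = 0.5 * (theory["delta_bin_lo"] + theory["delta_bin_hi"])
        ax.plot(c, theory["theory_F"], "k--", label="theory F(delta)")
    else:
        ax.plot(centers, table["rate"], "-o", label="network")
        ax.plot(centers, table["theory_F"], "k--", label="theory F(delta)")
    ax.set_xlabel(r"common-feature distance $\delta$")
    ax.set_ylabel("assignment error rate")
    ax.legend(fontsize=8)
    return _save(fig, out, fmt)


def _save(fig, out: str | Path, fmt: str) -> Path:
    if fmt not in ("png", "svg", "pdf"):
        raise ValueError(f"unsupported format {fmt!r}")
    out = Path(out).with_suffix(f".{fmt}")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


_PLOTTERS = {
    "assignment": (plot_assignment_rates, None),
    "rf_sweep": (plot_rf_sweep, None),
    "multiregion_map": (plot_multiregion_map, 0),  # index column
    "binned_rates": (plot_binned_rates, None),
}


def make_figures(tables: dict[str, str | Path], out_dir: str | Path, fmt: str = "png") -> list[Path]:
    """Render every recognized table kind to an image file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for kind, path in tables.items():
        if kind not in _PLOTTERS:
            raise ValueError(f"unknown table kind {kind!r}; known: {sorted(_PLOTTERS)}")
        plotter, index_col = _PLOTTERS[kind]
        table = pd.read_csv(path, index_col=index_col, comment="#")
        written.append(plotter(table, out_dir / kind, fmt))
    return written
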