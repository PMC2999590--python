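"""Convergence diagnostics: trace plots and autocorrelation summaries.

The chain protocol has no automated stopping rule; sampled values are
inspected visually, supported by lag-autocorrelation summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sampler import Trace

__all__ = ["autocorrelation", "autocorr_summary", "plot_trace"]


def autocorrelation(x: np.ndarray, max_lag: int = 50) -> np.ndarray:
    """Sample autocorrelation function up to ``max_lag`` (lag 0 included)."""
    x = np.asarray(x, float)
    x = x - x.mean()
    n = len(x)
    denom = float(x @ x)
    if denom == 0.0:
        return np.concatenate([[1.0], np.zeros(min(max_lag, n - 1))])
    return np.array([1.0] + [float(x[k:] @ x[:-k]) / denom for k in range(1, min(max_lag, n - 1) + 1)])


def autocorr_summary(trace: Trace, lags=(1, 10, 50)) -> pd.DataFrame:
    """Lag autocorrelations of the scalar chains and each inclusion indicator."""
    series = {"sigma": trace.sigma, "log_psi_int": trace.log_psi_int, "loglik": trace.loglik}
    for j, name in enumerate(trace.selectable_names):
        series[f"eff.{name}"] = trace.eff[:, j].astype(float)
    rows = []
    for name, x in series.items():
        acf = autocorrelation(x, max_lag=max(lags))
        rows.append({"series": name, **{f"lag{k}": acf[k] if k < len(acf) else np.nan for k in lags}})
    return pd.DataFrame(rows)


def plot_trace(trace: Trace, path=None, series=("sigma", "log_psi_int", "loglik")):
    """Trace plots for selected scalar series; saves to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = {"sigma": trace.sigma, "log_psi_int": trace.log_psi_int, "loglik": trace.loglik}
    series = [s for s in series if s in data]
    fig, axes = plt.subplots(len(series), 1, figsize=(8, 2.2 * len(series)), squeeze=False)
    for ax, name in zip(axes[:, 0], series):
        ax.plot(data[name], lw=0.4)
        ax.set_ylabel(name)
    axes[-1, 0].set_xlabel("retained iteration")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
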