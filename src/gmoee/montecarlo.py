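"""Monte Carlo comparison of the five GMO-EE estimators.

``run_study`` draws replicated samples from chosen true parameter
vectors, applies each estimator, and tabulates mean bias and mean squared
error per (parameter vector, n, estimator, parameter) cell, together with
the per-cell Monte Carlo standard error of the bias.

Design notes
------------
* Per-replicate seeds are spawned from the master seed via
  ``numpy.random.SeedSequence``, and all estimators within a replicate
  see the *same* sample (a paired design, which sharpens between-
  estimator comparisons).
* Each fit starts from the true parameter vector plus a small number of
  Latin-hypercube starts (``n_starts`` in total).  Replicates whose fit
  raises or fails to converge are dropped and counted per cell; a cell
  with zero converged replicates is reported with NaN summaries, never
  silently zero.
* The default replication count is 1000 — large enough that the
  per-cell Monte Carlo bands (sd/sqrt(reps)) are informative while a
  full default grid stays desk-scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ParamVector, Sample, rvs
from .estimation import METHODS

__all__ = ["SimDesign", "run_study", "summarize", "PARAM_NAMES", "DEFAULT_ETAS"]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("alpha", "lambda", "theta", "beta")

#: the three study parameter vectors
DEFAULT_ETAS = (
    ParamVector(0.4, 0.8, 1.0, 0.5),
    ParamVector(0.5, 0.7, 3.0, 0.9),
    ParamVector(0.2, 0.5, 2.0, 0.75),
)

DEFAULT_NS = (50, 100, 150, 200, 250, 500, 750, 1000)


@dataclass(frozen=True)
class SimDesign:
    """Configuration of a bias/MSE simulation study."""

    etas: tuple[ParamVector, ...] = DEFAULT_ETAS
    ns: tuple[int, ...] = DEFAULT_NS
    reps: int = 1000
    seed: int = 0
    estimators: tuple[str, ...] = ("MLE", "LSE", "WLSE", "CvME", "ADE")
    n_starts: int = 3  # true-value start + (n_starts - 1) LHS starts

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        unknown = set(self.estimators) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown estimators: {sorted(unknown)}")

    @classmethod
    def from_config(cls, path) -> "SimDesign":
        """Build a design from a ``key = value`` text config.

        Recognized keys: ``etas`` (semicolon-separated ``a,l,th,b``
        quadruples), ``ns`` (comma-separated), ``reps``, ``seed``,
        ``estimators`` (comma-separated), ``n_starts``.  Lines starting
        with ``#`` are comments; unknown keys raise.
        """
        kwargs: dict = {}
        for lineno, raw in enumerate(open(path, encoding="utf-8"), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = (t.strip() for t in line.partition("="))
            if key == "etas":
                kwargs["etas"] = tuple(
                    ParamVector(*(float(v) for v in quad.split(",")))
                    for quad in value.split(";") if quad.strip()
                )
            elif key == "ns":
                kwargs["ns"] = tuple(int(v) for v in value.split(","))
            elif key in ("reps", "seed", "n_starts"):
                kwargs[key] = int(value)
            elif key == "estimators":
                kwargs["estimators"] = tuple(
                    v.strip().upper().replace("CVME", "CvME")
                    for v in value.split(",")
                )
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        return cls(**kwargs)


def _fit_one(method: str, sample: Sample, eta_true: ParamVector,
             n_starts: int, seed: int):
    kwargs = dict(
        starts=max(n_starts - 1, 0),
        seed=seed,
        extra_starts=eta_true.as_array()[None, :],
    )
    if method == "MLE":
        kwargs["compute_se"] = False
    return METHODS[method](sample, **kwargs)


def run_study(design: SimDesign, progress: bool = False) -> pd.DataFrame:
    """Run the full study; returns one row per simulation cell.

    Columns: eta_index, n, estimator, parameter, true_value, mean_bias,
    mse, mc_se (Monte Carlo standard error of the mean bias), n_converged,
    n_failed.
    """
    root = np.random.SeedSequence(design.seed)
    rows = []
    for ei, eta in enumerate(design.etas):
        truth = eta.as_array()
        for n in design.ns:
            # errors per estimator: list of eta_hat - truth vectors
            errors: dict[str, list[np.ndarray]] = {m: [] for m in design.estimators}
            failed = {m: 0 for m in design.estimators}
            rep_seqs = np.random.SeedSequence(
                entropy=root.entropy, spawn_key=(ei, n)
            ).spawn(design.reps)
            for r, seq in enumerate(rep_seqs):
                child = np.random.default_rng(seq)
                sample = rvs(eta, n, seed=child)
                fit_seed = int(seq.generate_state(1)[0] % (2 ** 31))
                for m in design.estimators:
                    try:
                        fr = _fit_one(m, sample, eta, design.n_starts, fit_seed)
                    except Exception:
                        failed[m] += 1
                        continue
                    if not fr.converged:
                        failed[m] += 1
                        continue
                    errors[m].append(fr.eta_hat.as_array() - truth)
                if progress and (r + 1) % 100 == 0:
                    logger.info("eta%d n=%d: %d/%d replicates", ei + 1, n, r + 1, design.reps)
            for m in design.estimators:
                errs = np.asarray(errors[m])
                for pj, pname in enumerate(PARAM_NAMES):
                    if errs.size == 0:
                        bias = mse = mc_se = np.nan
                        n_conv = 0
                    else:
                        e = errs[:, pj]
                        bias = float(np.mean(e))
                        mse = float(np.mean(e ** 2))
                        mc_se = float(np.std(e, ddof=1) / np.sqrt(e.size)) if e.size > 1 else np.nan
                        n_conv = int(e.size)
                    rows.append({
                        "eta_index": ei + 1,
                        "n": n,
                        "estimator": m,
                        "parameter": pname,
                        "true_value": float(truth[pj]),
                        "mean_bias": bias,
                        "mse": mse,
                        "mc_se": mc_se,
                        "n_converged": n_conv,
                        "n_failed": failed[m],
                    })
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame, fmt: str = "dataframe"):
    """Pivot cell records into the study layout.

    Rows are (eta_index, n, estimator); columns are the mean bias of the
    four parameters followed by their MSEs.  ``fmt`` selects the output:
    ``"dataframe"`` (default), ``"csv"`` or ``"markdown"``.
    """
    cols = [f"bias_{p}" for p in PARAM_NAMES] + [f"mse_{p}" for p in PARAM_NAMES]
    if table.empty:
        wide = pd.DataFrame(columns=["eta_index", "n", "estimator"] + cols)
    else:
        bias = table.pivot_table(
            index=["eta_index", "n", "estimator"], columns="parameter",
            values="mean_bias", sort=False,
        )
        mse = table.pivot_table(
            index=["eta_index", "n", "estimator"], columns="parameter",
            values="mse", sort=False,
        )
        bias = bias.reindex(columns=list(PARAM_NAMES)).add_prefix("bias_")
        mse = mse.reindex(columns=list(PARAM_NAMES)).add_prefix("mse_")
        wide = pd.concat([bias, mse], axis=1).reset_index()
        wide = wide[["eta_index", "n", "estimator"] + cols]
    if fmt == "dataframe":
        return wide
    if fmt == "csv":
        return wide.to_csv(index=False)
    if fmt == "markdown":
        return wide.to_markdown(index=False)
    raise ValueError(f"unknown format {fmt!r}")
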