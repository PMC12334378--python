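"""Data ingestion, fixture generation and report writing.

CSV is the sole tabular interchange format (decimal point, UTF-8).  Every
run can be reproduced from its emitted config snapshot and seed alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sem_core import ModelSpec, mediation_spec
from .simgen import EMPIRICAL_GAMMA0, GammaSet, PopulationParameters, generate_dataset

log = logging.getLogger("modinvar")


@dataclass
class DatasetTable:
    """A rectangular indicator table plus moderator with provenance."""

    data: pd.DataFrame
    moderator_name: str
    standardized: bool
    provenance: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def indicators(self) -> pd.DataFrame:
        return self.data.drop(columns=[self.moderator_name])

    @property
    def moderator(self) -> np.ndarray:
        return self.data[self.moderator_name].to_numpy(dtype=float)


def read_dataset(
    path: str | Path,
    moderator_name: str = "Z",
    standardize_moderator: bool = True,
) -> DatasetTable:
    """Load a CSV of indicators plus one moderator column.

    Missing cells and non-numeric entries are rejected with the offending
    row and column named.  When ``standardize_moderator`` is set the
    moderator is scaled to mean 0, SD 1 (recommended: the moderation
    intercepts gamma0 are then the expected parameters at the average
    moderator level)."""
    path = Path(path)
    df = pd.read_csv(path)
    if moderator_name not in df.columns:
        raise ValueError(f"moderator column {moderator_name!r} not in {path.name}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric or missing value at row {row}, column {col!r}"
            )
        df[col] = numeric.astype(float)
    standardized = False
    if standardize_moderator:
        m = df[moderator_name]
        sd = m.std(ddof=0)
        if sd == 0:
            raise ValueError("moderator is constant; cannot standardize")
        df[moderator_name] = (m - m.mean()) / sd
        standardized = True
        log.info("standardized moderator %s to mean 0, sd 1", moderator_name)
    return DatasetTable(
        data=df,
        moderator_name=moderator_name,
        standardized=standardized,
        provenance={"source": str(path), "standardized_moderator": standardized},
    )


# ---------------------------------------------------------------------------
# Packaged fixture
# ---------------------------------------------------------------------------

#: Fixture moderation: parallel intercept drifts per construct (a latent-
#: mean moderation in disguise) plus one genuinely moderated residual
#: variance (second indicator of M, log scale).  Values sit in the
#: 0.2-0.4-per-unit-Z range typical of the worked example.
FIXTURE_SLOPES = {
    "alpha_x1": 0.26, "alpha_x2": 0.25, "alpha_x3": 0.25,
    "alpha_m1": 0.24, "alpha_m2": 0.20, "alpha_m3": 0.17,
    "alpha_y1": -0.33, "alpha_y2": -0.32, "alpha_y3": -0.38,
    "theta_m2": 0.20,
}


def fixture_population(spec: ModelSpec | None = None) -> PopulationParameters:
    """Deterministic (no-heterogeneity) population mimicking the worked
    example: three 3-indicator constructs, parallel intercept moderation,
    one moderated residual variance."""
    spec = spec or mediation_spec()
    gammas = {
        n: GammaSet(
            gamma0=EMPIRICAL_GAMMA0[n],
            gamma1=FIXTURE_SLOPES.get(n, 0.0),
            sigma_het=0.0,
        )
        for n in spec.param_names
    }
    return PopulationParameters(gammas=gammas, spec=spec)


def make_fixture(seed: int = 0, n: int = 399) -> DatasetTable:
    """Generate the packaged example dataset (default N = 399)."""
    spec = mediation_spec()
    pop = fixture_population(spec)
    y, z = generate_dataset(pop, n, seed)
    df = pd.DataFrame(y, columns=spec.indicator_names)
    df["Z"] = z
    return DatasetTable(
        data=df,
        moderator_name="Z",
        standardized=False,
        provenance={
            "source": "modinvar.dataio.make_fixture",
            "seed": seed,
            "n": n,
            "population": pop.provenance(),
        },
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_report(results: dict, out_dir: str | Path) -> list[Path]:
    """Write tables (CSV), a machine-readable JSON summary and a decision
    log to ``out_dir``.  ``results`` maps names to DataFrames/Series (CSV)
    or JSON-serialisable objects."""
    if not results:
        raise ValueError("no results to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {}
    for name, obj in results.items():
        if isinstance(obj, (pd.DataFrame, pd.Series)):
            p = out / f"{name}.csv"
            obj.to_csv(p)
            written.append(p)
            log.info("wrote table %s", p)
        else:
            summary[name] = obj
    p = out / "summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=1, default=_jsonable)
    written.append(p)
    return written


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.DataFrame, pd.Series)):
        return json.loads(obj.to_json())
    return str(obj)
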