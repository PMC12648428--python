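"""Two-level multivariate-normal data generator for paired regional brain maps.

A dataset is a balanced table of one value per (participant, region, modality),
e.g. a receptor binding potential (BPND) and cerebral blood flow (CBF) measured
in the same R regions of the same n participants.  Participants are i.i.d.
draws from a 2R-dimensional multivariate normal whose correlation matrix has
exactly four parameters:

* ``rho_within[m]`` — compound (exchangeable) correlation between any two
  regions within modality ``m``;
* ``rho_cross_same`` — correlation between the two modalities in the *same*
  region, i.e. the *marginal* cross-modality correlation;
* ``rho_cross_diff`` — correlation between the two modalities in *different*
  regions.

Decomposing each measurement into a participant-level modality mean (shared by
all regions) plus region-level noise shows that the cross-modality correlation
of the noise alone — the *conditional* correlation — is

    (rho_cross_same - rho_cross_diff) / sqrt((1-rho_within[0])(1-rho_within[1]))

Scenarios A–E toggle region-specific means and variances and the presence of a
cross-modality correlation, which is what makes across-regions and
across-participants correlation estimates diverge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenerativeSpec",
    "RegionalTable",
    "solve_cross_correlations",
    "build_covariance",
    "scenario_spec",
    "simulate_dataset",
    "load_fixture",
    "SCENARIO_LABELS",
]

SCENARIO_LABELS = ("A", "B", "C", "D", "E")

DEFAULT_MODALITIES = ("BPND", "CBF")


def _as_2xR(x, R: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (2, R):
        raise ValueError(f"{name} must have shape (2, {R}), got {arr.shape}")
    return arr


@dataclass(frozen=True)
class GenerativeSpec:
    """Full data-generating mechanism for one simulation scenario.

    ``mu`` and ``sigma`` are (2, R) arrays indexed (modality, region) in the
    units of each modality; the four correlation parameters are unitless.
    """

    region_labels: tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray
    rho_within: tuple[float, float]
    rho_cross_same: float
    rho_cross_diff: float
    region_specific_mean: bool = True
    region_specific_variance: bool = True
    cross_modality_correlation: bool = True
    modalities: tuple[str, str] = DEFAULT_MODALITIES
    label: str | None = None

    def __post_init__(self):
        R = len(self.region_labels)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        object.__setattr__(self, "mu", _as_2xR(self.mu, R, "mu"))
        object.__setattr__(self, "sigma", _as_2xR(self.sigma, R, "sigma"))
        object.__setattr__(self, "rho_within", tuple(float(r) for r in self.rho_within))
        self.validate()

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def marginal_correlation(self) -> float:
        """Cross-modality same-region correlation (subject noise included)."""
        return self.rho_cross_same

    @property
    def conditional_correlation(self) -> float:
        """Cross-modality correlation of the region-level (measurement) noise."""
        denom = np.sqrt((1.0 - self.rho_within[0]) * (1.0 - self.rho_within[1]))
        return (self.rho_cross_same - self.rho_cross_diff) / denom

    def validate(self) -> None:
        if np.any(self.sigma <= 0):
            raise ValueError("all sigma must be > 0")
        corrs = (*self.rho_within, self.rho_cross_same, self.rho_cross_diff)
        if not all(-1.0 < c < 1.0 for c in corrs):
            raise ValueError(f"correlation parameters must lie in (-1, 1): {corrs}")
        if not -1.0 < self.conditional_correlation < 1.0:
            raise ValueError(
                "implied conditional correlation "
                f"{self.conditional_correlation:.4f} outside (-1, 1)"
            )
        if not self.region_specific_mean:
            for m in range(2):
                if not np.allclose(self.mu[m], self.mu[m, 0]):
                    raise ValueError(
                        "region_specific_mean is False but mu varies over regions"
                    )
        if not self.region_specific_variance:
            for m in range(2):
                if not np.allclose(self.sigma[m], self.sigma[m, 0]):
                    raise ValueError(
                        "region_specific_variance is False but sigma varies over regions"
                    )
        if not self.cross_modality_correlation and not (
            self.rho_cross_same == 0.0 and self.rho_cross_diff == 0.0
        ):
            raise ValueError(
                "cross_modality_correlation is False but cross correlations are non-zero"
            )
        # PD check: Cholesky of the implied correlation matrix must succeed.
        try:
            np.linalg.cholesky(_correlation_matrix(self))
        except np.linalg.LinAlgError as err:
            raise ValueError(
                "implied 2Rx2R correlation matrix is not positive definite for "
                f"rho_within={self.rho_within}, rho_cross_same={self.rho_cross_same}, "
                f"rho_cross_diff={self.rho_cross_diff}"
            ) from err


def _correlation_matrix(spec: GenerativeSpec) -> np.ndarray:
    """2R x 2R correlation matrix, modality-major ordering (all of modality 0,
    then all of modality 1, regions in fixture order within each block)."""
    R = spec.n_regions
    C = np.empty((2 * R, 2 * R))
    eye = np.eye(R)
    for m in range(2):
        blk = np.full((R, R), spec.rho_within[m])
        np.fill_diagonal(blk, 1.0)
        C[m * R:(m + 1) * R, m * R:(m + 1) * R] = blk
    cross = np.full((R, R), spec.rho_cross_diff)
    cross += (spec.rho_cross_same - spec.rho_cross_diff) * eye
    C[:R, R:] = cross
    C[R:, :R] = cross.T
    return C


def build_covariance(spec: GenerativeSpec) -> np.ndarray:
    """Covariance matrix of the 2R-vector (modality-major ordering).

    Entry ((m, r), (m', r')) equals ``sigma[m][r] * sigma[m'][r'] * c`` where
    ``c`` is 1 on the diagonal, ``rho_within[m]`` within a modality,
    ``rho_cross_same`` across modalities in the same region and
    ``rho_cross_diff`` otherwise.
    """
    spec.validate()
    s = spec.sigma.reshape(-1)  # modality-major, matches _correlation_matrix
    return _correlation_matrix(spec) * np.outer(s, s)


def solve_cross_correlations(
    target_marginal: float,
    target_conditional: float,
    rho_within: tuple[float, float],
    n_regions: int = 18,
) -> tuple[float, float]:
    """Cross-modality correlation parameters hitting given marginal/conditional
    targets.

    The marginal correlation is ``rho_cross_same`` itself; inverting the
    conditional-correlation identity gives
    ``rho_cross_diff = marginal - conditional * sqrt((1-rw0)(1-rw1))``.
    Raises ``ValueError`` when the resulting 2R x 2R correlation matrix is not
    positive definite (incompatible targets).
    """
    if not (-1.0 < target_marginal < 1.0 and -1.0 < target_conditional < 1.0):
        raise ValueError("targets must lie in (-1, 1)")
    rw0, rw1 = rho_within
    if not (0.0 <= rw0 < 1.0 and 0.0 <= rw1 < 1.0):
        raise ValueError("rho_within values must lie in [0, 1)")
    rho_cross_same = float(target_marginal)
    rho_cross_diff = float(target_marginal - target_conditional * np.sqrt((1 - rw0) * (1 - rw1)))
    probe = GenerativeSpec(
        region_labels=tuple(f"r{i}" for i in range(n_regions)),
        mu=np.zeros((2, n_regions)),
        sigma=np.ones((2, n_regions)),
        rho_within=(rw0, rw1),
        rho_cross_same=rho_cross_same,
        rho_cross_diff=rho_cross_diff,
        region_specific_mean=False,
        region_specific_variance=False,
        cross_modality_correlation=True,
    )  # __post_init__ validates positive definiteness
    del probe
    return rho_cross_same, rho_cross_diff


def load_fixture(path: str | Path | None = None) -> dict:
    """Load the generative fixture (shipped default when ``path`` is None)."""
    if path is None:
        ref = resources.files("mapcorr") / "fixtures" / "default.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    fx = yaml.safe_load(text)
    for key in ("modalities", "regions", "baseline", "rho_within",
                "mean_profile", "sd_profile", "scenarios"):
        if key not in fx:
            raise ValueError(f"fixture is missing required key {key!r}")
    R = len(fx["regions"])
    for m in fx["modalities"]:
        for block in ("mean_profile", "sd_profile"):
            if len(fx[block][m]) != R:
                raise ValueError(f"fixture {block}[{m}] must have {R} entries")
    return fx


def scenario_spec(label: str, fixture: str | Path | dict | None = None) -> GenerativeSpec:
    """Build the GenerativeSpec for scenario ``label`` in {A, B, C, D, E}.

    Region-specific means/variances come from the fixture profiles; otherwise
    the modality baseline is used for every region.  Cross-modality
    correlations are solved from the scenario's marginal/conditional targets.
    """
    label = str(label).upper()
    fx = fixture if isinstance(fixture, dict) else load_fixture(fixture)
    if label not in fx["scenarios"]:
        known = ", ".join(sorted(fx["scenarios"]))
        raise ValueError(f"unknown scenario {label!r}; known scenarios: {known}")
    sc = fx["scenarios"][label]
    modalities = tuple(fx["modalities"])
    regions = tuple(fx["regions"])
    R = len(regions)
    rho_within = tuple(float(fx["rho_within"][m]) for m in modalities)

    if sc["region_specific_mean"]:
        mu = np.array([fx["mean_profile"][m] for m in modalities], dtype=float)
    else:
        mu = np.array([[float(fx["baseline"][m]["mean"])] * R for m in modalities])
    if sc["region_specific_variance"]:
        sigma = np.array([fx["sd_profile"][m] for m in modalities], dtype=float)
    else:
        sigma = np.array([[float(fx["baseline"][m]["sd"])] * R for m in modalities])

    if sc["cross_modality_correlation"]:
        rcs, rcd = solve_cross_correlations(
            float(sc["marginal"]), float(sc["conditional"]), rho_within, n_regions=R
        )
    else:
        rcs, rcd = 0.0, 0.0

    return GenerativeSpec(
        region_labels=regions,
        mu=mu,
        sigma=sigma,
        rho_within=rho_within,
        rho_cross_same=rcs,
        rho_cross_diff=rcd,
        region_specific_mean=bool(sc["region_specific_mean"]),
        region_specific_variance=bool(sc["region_specific_variance"]),
        cross_modality_correlation=bool(sc["cross_modality_correlation"]),
        modalities=modalities,
        label=label,
    )


class RegionalTable:
    """Balanced long-format table of one value per (participant, region, modality).

    Stored internally as a dense ``(n, M, R)`` array for speed; ``to_frame`` /
    ``from_frame`` convert to and from the long pandas representation with
    columns ``participant_id, region, modality, value``.
    """

    COLUMNS = ("participant_id", "region", "modality", "value")

    def __init__(self, values: np.ndarray, participants, regions, modalities):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3:
            raise ValueError("values must be (n_participants, n_modalities, n_regions)")
        self.values = values
        self.participants = tuple(str(p) for p in participants)
        self.regions = tuple(str(r) for r in regions)
        self.modalities = tuple(str(m) for m in modalities)
        n, M, R = values.shape
        if (n, M, R) != (len(self.participants), len(self.modalities), len(self.regions)):
            raise ValueError("values shape inconsistent with labels")

    # -- basic protocol ----------------------------------------------------
    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[2]

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RegionalTable)
            and self.participants == other.participants
            and self.regions == other.regions
            and self.modalities == other.modalities
            and np.array_equal(self.values, other.values)
        )

    # -- views -------------------------------------------------------------
    def modality_matrix(self, modality: str) -> np.ndarray:
        """(n, R) matrix of one modality's values."""
        return self.values[:, self.modalities.index(modality), :]

    def regional_means(self) -> np.ndarray:
        """(M, R) participant-averaged map for each modality."""
        return self.values.mean(axis=0)

    def subset_participants(self, idx) -> "RegionalTable":
        idx = np.asarray(idx)
        return RegionalTable(
            self.values[idx], [self.participants[i] for i in idx],
            self.regions, self.modalities,
        )

    def subset_modality(self, modality: str) -> "RegionalTable":
        j = self.modalities.index(modality)
        return RegionalTable(
            self.values[:, [j], :], self.participants, self.regions, (modality,)
        )

    # -- long-format conversion --------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        n, M, R = self.values.shape
        return pd.DataFrame({
            "participant_id": np.repeat(self.participants, M * R),
            "region": np.tile(np.repeat(self.regions, 1), n * M),
            "modality": np.tile(np.repeat(self.modalities, R), n),
            "value": self.values.reshape(-1),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   modalities: tuple[str, ...] | None = None) -> "RegionalTable":
        missing = [c for c in cls.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        if modalities is not None:
            bad = sorted(set(df["modality"]) - set(modalities))
            if bad:
                raise ValueError(
                    f"unknown modality labels {bad}; allowed: {list(modalities)}"
                )
        dup = df.duplicated(subset=["participant_id", "region", "modality"])
        if dup.any():
            row = df.loc[dup.idxmax()]
            raise ValueError(
                "duplicated cell (participant_id={0[participant_id]!r}, "
                "region={0[region]!r}, modality={0[modality]!r})".format(row)
            )
        parts = list(dict.fromkeys(df["participant_id"].astype(str)))
        regions = list(dict.fromkeys(df["region"].astype(str)))
        mods = list(modalities) if modalities is not None \
            else list(dict.fromkeys(df["modality"].astype(str)))
        wide = df.pivot_table(index="participant_id", columns=["modality", "region"],
                              values="value", aggfunc="first")
        expected = len(parts) * len(regions) * len(mods)
        if len(df) != expected or wide.isna().any().any():
            raise ValueError(
                f"unbalanced table: expected {expected} rows "
                f"({len(parts)} participants x {len(regions)} regions x "
                f"{len(mods)} modalities), got {len(df)} with "
                f"{int(wide.isna().sum().sum())} missing cells"
            )
        values = np.empty((len(parts), len(mods), len(regions)))
        for mi, m in enumerate(mods):
            block = wide[m].reindex(index=parts, columns=regions)
            values[:, mi, :] = block.to_numpy()
        return cls(values, parts, regions, mods)


def simulate_dataset(spec: GenerativeSpec, n: int,
                     seed: int | np.random.Generator | np.random.SeedSequence) -> RegionalTable:
    """Draw a balanced dataset of ``n`` participants from ``spec``.

    Sampling is by Cholesky factor of the full 2R x 2R covariance matrix, which
    also covers negative ``rho_cross_diff`` (a random-effect representation
    could not).  The same (spec, n, seed) always yields an identical table.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = np.linalg.cholesky(build_covariance(spec))
    R = spec.n_regions
    z = rng.standard_normal((n, 2 * R))
    draws = z @ L.T + spec.mu.reshape(-1)
    values = draws.reshape(n, 2, R)
    participants = [f"p{i + 1:03d}" for i in range(n)]
    return RegionalTable(values, participants, spec.region_labels, spec.modalities)
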