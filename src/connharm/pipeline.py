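"""End-to-end pipeline driver: synth -> build -> alter -> harmonics -> metrics.

``PipelineConfig`` gathers every tunable with its default (smoothing
f_i = 0, threshold z_C = 1, kernel width 2, trimming/callosectomy/
anisotropy percentages 0, K = 100 harmonics, N = 16 MI bins, N_surr = 100
surrogates over harmonics 7..11).  ``run_pipeline`` executes the stages in
order, is deterministic given the seeds, and (when an output directory is
given) writes every artifact plus a provenance record of the resolved
configuration and stage counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import alterations, build, harmonics, io, metrics, synth
from .types import InvalidParameterError

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run."""

    synth: synth.SynthBrainConfig = field(default_factory=synth.SynthBrainConfig)
    # connectome construction
    min_track_length_mm: float = 10.0
    extension_mm: float = 3.0
    max_gap_mm: float = 5.0
    kernel_width: int = 2  # local diffusion kernel width (1 or 2)
    z_C: float = 1.0  # adjacency weight threshold, in weight SDs
    # alterations (defaults = no alteration)
    f_i: int = 0  # mesh smoothing iterations
    eta: float = 0.0  # % long-range connections trimmed
    eta_order: str = "descending"
    kappa: float = 0.0  # % inter-hemispheric connections removed
    kappa_order: str = "random"
    rho: float = 0.0  # % local edges removed
    rho_order: str = "random"
    randomize_scheme: Optional[str] = None  # inter | intra | inter+intra | global
    swaps_per_edge: int = 10
    alteration_seed: int = 0
    # harmonics and metrics
    K: int = 100
    zero_tol: float = 1e-8
    N_bins: int = 16
    k0: int = 7
    n_k: int = 5
    N_surr: int = 100

    def validate(self) -> None:
        if self.kernel_width not in (1, 2):
            raise InvalidParameterError("kernel_width must be 1 or 2")
        if self.kappa_order == "random" and self.kappa >= 100:
            raise InvalidParameterError(
                "random callosectomy is capped at 99% to keep hemispheres connected"
            )
        for name, hi in (("eta", 100), ("rho", 100)):
            v = getattr(self, name)
            if not 0 <= v <= hi:
                raise InvalidParameterError(f"{name} must lie in [0, {hi}]")
        if self.randomize_scheme is not None and self.randomize_scheme not in alterations.SCHEMES:
            raise InvalidParameterError(f"unknown scheme {self.randomize_scheme!r}")
        if self.f_i < 0:
            raise InvalidParameterError("f_i must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    mesh: object
    hemisphere: np.ndarray
    parcellation: object
    rsn: object
    weighted: object
    local: object
    longrange: object
    combined: object
    basis: object
    r: float
    mi_table: pd.DataFrame
    provenance: dict


def run_pipeline(config: PipelineConfig, out_dir: Optional[Path] = None) -> PipelineResult:
    """Execute the full analysis chain on a synthetic brain.

    Stages: generate brain + parcellation + RSN map and streamlines; smooth
    the mesh (f_i); build local and long-range connectivity; z-score and
    threshold at z_C; apply trimming / callosectomy / anisotropy /
    randomization as configured; combine; eigendecompose the graph
    Laplacian; compute the MI of each harmonic with the RSN map.
    """
    config.validate()
    sc = config.synth

    mesh, hemisphere, parcellation = synth.make_brain(sc)
    rsn = synth.make_rsn(parcellation, sc.n_rsn_patches, seed=sc.seed + 10)
    streamlines = synth.make_streamlines(mesh, hemisphere, sc, parcellation, rsn)

    if config.f_i > 0:
        mesh = alterations.smooth_mesh(mesh, config.f_i)

    weighted = build.build_long_range(
        streamlines,
        mesh,
        min_track_length_mm=config.min_track_length_mm,
        extension_mm=config.extension_mm,
        max_gap_mm=config.max_gap_mm,
    )
    build.zscore_weights(weighted)
    longrange = build.threshold_long_range(weighted, config.z_C)
    local = build.build_local_adjacency(mesh, config.kernel_width)

    seed = config.alteration_seed
    if config.eta > 0:
        longrange = alterations.trim_long_range(
            longrange, weighted.Lbar, config.eta, config.eta_order, seed
        )
    if config.kappa > 0:
        longrange = alterations.callosectomy(
            longrange, hemisphere, config.kappa, config.kappa_order, seed,
            Lbar=weighted.Lbar,
        )
    if config.rho > 0:
        local = alterations.anisotropy(local, config.rho, config.rho_order, seed)
    if config.randomize_scheme is not None:
        longrange = alterations.randomize_long_range(
            longrange, hemisphere, config.randomize_scheme, seed,
            config.swaps_per_edge,
        )

    combined = build.combine(local, longrange)
    r = build.local_ratio(local, longrange)
    L = harmonics.graph_laplacian(combined.A)
    basis = harmonics.eigendecompose(L, min(config.K, mesh.m), config.zero_tol)

    mi = [
        metrics.mutual_information(basis.psi(k), rsn, config.N_bins).mi
        for k in range(1, basis.K + 1)
    ]
    mi_table = pd.DataFrame(
        {"harmonic": np.arange(1, basis.K + 1), "eigenvalue": basis.eigenvalues, "mi": mi}
    )

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_tracks": len(streamlines),
        "n_kept": weighted.n_kept,
        "n_discarded_short": weighted.n_discarded_short,
        "n_discarded_unresolved": weighted.n_discarded_unresolved,
        "n_discarded_selfloop": weighted.n_discarded_selfloop,
        "mu_C": weighted.mu_C,
        "sigma_C": weighted.sigma_C,
        "r": r,
        "zero_modes": harmonics.count_zero_modes(basis),
    }

    result = PipelineResult(
        config=config,
        mesh=mesh,
        hemisphere=hemisphere,
        parcellation=parcellation,
        rsn=rsn,
        weighted=weighted,
        local=local,
        longrange=longrange,
        combined=combined,
        basis=basis,
        r=r,
        mi_table=mi_table,
        provenance=provenance,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_mesh(result.mesh, out_dir / "mesh.off")
    io.write_labels(result.hemisphere, out_dir / "hemisphere.txt")
    io.write_labels(result.parcellation.region_of, out_dir / "parcellation.txt")
    io.write_map(result.rsn.values, out_dir / "rsn.txt")
    io.write_sparse(result.weighted.C, out_dir / "C.mtx")
    io.write_sparse(result.weighted.Lbar, out_dir / "Lbar.mtx")
    io.write_sparse(result.local.A_l, out_dir / "A_local.mtx")
    io.write_sparse(result.longrange.A_c, out_dir / "A_longrange.mtx")
    io.write_sparse(result.combined.A, out_dir / "A_combined.mtx")
    np.savetxt(out_dir / "eigenvalues.txt", result.basis.eigenvalues)
    np.savetxt(out_dir / "eigenvectors.txt", result.basis.eigenvectors)
    result.mi_table.to_csv(out_dir / "mi.csv", index=False)
    io.write_json(result.provenance, out_dir / "provenance.json")
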