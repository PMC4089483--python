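"""Pipeline configuration.

Every tunable constant of the method lives here with its default, so a run
is fully described by (inputs, config, seed).  Configs load from YAML/JSON
mappings; unknown keys are rejected to catch typos early.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

# Correlation threshold used when curating real-map training cases: a case
# enters a training set only if the deposited-ligand map and the difference
# map correlate at or above this value.  Plays no role on synthetic data.
TRAINING_CC_FILTER = 0.75


@dataclass
class GridConfig:
    """Free-atom placement and sparse-grid thinning."""

    #: placement floor, in multiples of the map sigma_level
    floor_sigma: float = 1.0
    #: free atoms must attach to an existing atom within this window (A)
    attach_min: float = 1.2
    attach_max: float = 1.7
    #: hard exclusion radius between free atoms (A)
    exclusion: float = 1.2
    #: maximum number of free atoms placed
    atom_cap: int = 250
    #: snap radius around the user's approximate blob location (A)
    seed_snap_radius: float = 5.0
    #: single-linkage cutoff for the initial cluster selection (A)
    cluster_cutoff: float = 2.0
    #: relaxed cutoff for re-clustering after thinning (A)
    recluster_cutoff: float = 2.3
    #: half-width of the strict local-maximum window in the sigma profile
    peak_window: int = 3
    #: peaks must exceed mean(sigma) + peak_min_sd * SD(sigma)
    peak_min_sd: float = 1.0
    #: maximum number of thinning thresholds
    max_thresholds: int = 5
    #: grids smaller than this are discarded
    min_grid_points: int = 3


@dataclass
class ConformerConfig:
    """Torsion-driving conformer generation."""

    max_conformers: int = 200
    step_deg: float = 60.0
    #: non-bonded pairs closer than this reject a conformer (A)
    clash_distance: float = 2.0
    #: exhaustive torsion-grid enumeration up to this many states;
    #: beyond it, seeded random sampling of the grid is used
    enumeration_limit: int = 7776
    #: random states sampled per requested conformer when sampling
    oversample: int = 4
    seed: int = 20140629


@dataclass
class FeatureConfig:
    """Descriptor computation."""

    #: pseudo-bond cutoff between free atoms (A)
    pseudo_bond_cutoff: float = 1.8
    #: Burden-matrix diagonal for pseudo-atoms (carbon-equivalent)
    pseudo_atom_diagonal: float = 6.0


@dataclass
class TrainConfig:
    """Cross-entropy weight training."""

    population: int = 60
    elite: int = 10
    iterations: int = 40
    initial_sd: float = 0.3
    seed: int = 0


@dataclass
class AlignConfig:
    """Genetic-algorithm flexible superposition."""

    population: int = 30
    generations: int = 30
    elite: int = 6
    #: uniform shake applied after crossover (degrees)
    shake_deg: float = 10.0
    #: width of the saturating per-pair reward (A)
    score_sigma: float = 0.5
    #: nearest-neighbour superposition refreshes per evaluation
    icp_iterations: int = 3
    seed: int = 0


@dataclass
class RefineConfig:
    """Real-space refinement."""

    max_iterations: int = 50
    tol: float = 1e-4
    mask_radius: float = 2.5
    #: initial step sizes for the coordinate-wise ascent
    step_translation: float = 0.3
    step_rotation_deg: float = 5.0
    step_torsion_deg: float = 10.0
    #: model resolution used when the map's nominal resolution is unknown (A)
    default_resolution: float = 1.5
    #: ascent-mask voxel budget; larger masks are subsampled by a stride
    max_mask_voxels: int = 8000


@dataclass
class PipelineConfig:
    """Top-level configuration for identification runs."""

    grid: GridConfig = field(default_factory=GridConfig)
    conformers: ConformerConfig = field(default_factory=ConformerConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    #: candidates handed to alignment + real-space refinement
    top_n: int = 20
    #: composite over conformers x grids: "min" or "mean"
    composite: str = "min"
    #: minimum heavy-atom count for library molecules
    min_heavy_atoms: int = 5

    @classmethod
    def fast(cls) -> "PipelineConfig":
        """Reduced GA/refinement settings for large screening batches."""
        cfg = cls()
        cfg.align.population = 8
        cfg.align.generations = 6
        cfg.align.elite = 3
        cfg.refine.max_iterations = 6
        cfg.refine.max_mask_voxels = 4000
        return cfg

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        for section, value in data.items():
            if not hasattr(cfg, section):
                raise ParameterError(f"unknown config section: {section!r}")
            current = getattr(cfg, section)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                names = {f.name for f in dataclasses.fields(current)}
                for key, v in value.items():
                    if key not in names:
                        raise ParameterError(
                            f"unknown config key: {section}.{key!r}"
                        )
                    setattr(current, key, v)
            else:
                setattr(cfg, section, value)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"config root must be a mapping: {path}")
        return cls.from_mapping(data)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
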