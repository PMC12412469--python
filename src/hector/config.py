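"""Run configuration: mapping + search parameters, presets, YAML round-trip.

A ``RunConfig`` bundles everything one invocation needs: the fingerprint
parameterization, the search funnel settings, and the seed.  The two
published parameter generations are available as presets ("v01", "v02");
loading a preset and dumping it reproduces every published value
exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .fingerprint import MapParams, preset as map_preset
from .rfactor import RFactorConfig
from .search import SearchConfig

__all__ = ["RunConfig", "run_preset"]


@dataclass
class RunConfig:
    map_params: MapParams
    search: SearchConfig
    seed: int = 0
    preset_name: str = "custom"

    def to_dict(self) -> dict:
        search = asdict(self.search)
        search["rfactor"] = asdict(self.search.rfactor)
        return {
            "preset": self.preset_name,
            "seed": self.seed,
            "map": self.map_params.to_dict(),
            "search": search,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        search_data = dict(data["search"])
        rf = search_data.pop("rfactor", None)
        search = SearchConfig(**search_data,
                              rfactor=RFactorConfig(**rf) if rf else RFactorConfig())
        return cls(
            map_params=MapParams.from_dict(data["map"]),
            search=search,
            seed=int(data.get("seed", 0)),
            preset_name=data.get("preset", "custom"),
        )

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def run_preset(name: str, seed: int = 0) -> RunConfig:
    """Full run configuration for a published parameter generation.

    "v02" pairs the second-generation maps with the symmetric top-5%
    search and its cutoffs; "v01" pairs the first-generation maps with
    the sequential lowest-50 band search at ±3 Å tolerance and the
    version-matched R-factor.
    """
    key = name.replace(".", "").lower()
    if key == "v02":
        return RunConfig(map_params=map_preset("v02"), search=SearchConfig(),
                         seed=seed, preset_name="v02")
    if key == "v01":
        search = SearchConfig(
            selection_mode="top_count", top_count=50, distance_tolerance=3.0,
            r_avg_cutoff=None, clique_rmsd_cutoff=None,
            rfactor=RFactorConfig(version="v01"),
        )
        return RunConfig(map_params=map_preset("v01"), search=search,
                         seed=seed, preset_name="v01")
    raise KeyError(f"unknown preset {name!r}; choose 'v01' or 'v02'")
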