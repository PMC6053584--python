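"""Sample-to-population assignments, groupings, and population coordinates."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class PopulationAssignment:
    """Maps samples to populations and, optionally, populations to groups."""

    sample_to_population: dict[str, str]
    population_to_group: dict[str, str] | None = None
    coordinates: pd.DataFrame | None = None  # columns: population, lat, lon

    populations: list[str] = field(init=False)

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for p in self.sample_to_population.values():
            seen.setdefault(p, None)
        self.populations = list(seen)
        if self.coordinates is not None:
            required = {"population", "lat", "lon"}
            if not required <= set(self.coordinates.columns):
                raise ValueError("coordinates need population, lat, lon columns")

    def samples_of(self, population: str) -> list[str]:
        return [
            s for s, p in self.sample_to_population.items() if p == population
        ]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.sample_to_population.values():
            out[p] = out.get(p, 0) + 1
        return out

    def group_of(self, population: str) -> str:
        if self.population_to_group is None:
            raise ValueError("no grouping defined")
        return self.population_to_group[population]

    def with_groups(self, mapping: dict[str, str]) -> "PopulationAssignment":
        return PopulationAssignment(
            dict(self.sample_to_population), dict(mapping), self.coordinates
        )


def read_population_map(path) -> PopulationAssignment:
    """TSV with columns sample_id, population and optional partition."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "population"} <= set(df.columns):
        raise ValueError("population map needs sample_id and population columns")
    s2p = dict(zip(df["sample_id"], df["population"]))
    groups = None
    if "partition" in df.columns and df["partition"].notna().any():
        pop_part = df.dropna(subset=["partition"]).drop_duplicates("population")
        groups = dict(zip(pop_part["population"], pop_part["partition"]))
    return PopulationAssignment(s2p, groups)


def write_population_map(assignment: PopulationAssignment, path) -> None:
    rows = []
    for s, p in assignment.sample_to_population.items():
        row = {"sample_id": s, "population": p}
        if assignment.population_to_group is not None:
            row["partition"] = assignment.population_to_group.get(p, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_coordinates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"population", "lat", "lon"} <= set(df.columns):
        raise ValueError("coordinates need population, lat, lon columns")
    return df
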