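"""Stage schemes: the ordered developmental stages of a cohort study.

A scheme lists the raw stages an observer records (egg, larval instars,
pupa, adult) and an optional order-preserving, many-to-one grouping onto
analysis stages.  Grouping is how studies with a temperature-dependent
instar count are put on a common footing: cohorts reared cold may need a
6th or 7th instar, and those extra instars are pooled with the 5th into a
single analysis stage so every treatment shares one stage structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError


@dataclass(frozen=True)
class StageScheme:
    """Ordered stage labels plus an optional raw->analysis grouping map.

    Parameters
    ----------
    stages:
        Raw stage labels in developmental order.  The first must be the
        egg stage and the last the adult stage.
    grouping:
        Maps each raw label to an analysis label.  Many-to-one and
        order-preserving: raw stages mapped to the same analysis stage
        must be contiguous, and a later raw stage never maps to an
        earlier analysis stage.  An empty map means identity.
    """

    stages: tuple[str, ...]
    grouping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ConfigError("scheme needs at least an egg and an adult stage")
        if len(set(self.stages)) != len(self.stages):
            raise ConfigError(f"duplicate stage labels in {self.stages}")
        if self.grouping:
            unknown = set(self.grouping) - set(self.stages)
            if unknown:
                raise ConfigError(f"grouping refers to unknown stages {sorted(unknown)}")
            # order preservation: analysis labels must appear in contiguous runs
            seq = [self.grouping.get(s, s) for s in self.stages]
            seen: set[str] = set()
            prev = None
            for label in seq:
                if label != prev and label in seen:
                    raise ConfigError(
                        f"grouping is not order-preserving: {label!r} re-appears"
                    )
                if label != prev:
                    seen.add(label)
                prev = label
            if seq[0] != self.stages[0] and self.stages[0] in self.grouping:
                # egg may be renamed but must stay first; contiguity already
                # guarantees it cannot merge with a later run
                pass

    # -- derived views -------------------------------------------------

    @property
    def egg(self) -> str:
        return self.stages[0]

    @property
    def adult(self) -> str:
        return self.stages[-1]

    @property
    def immature_stages(self) -> tuple[str, ...]:
        return self.stages[:-1]

    def analysis_label(self, stage: str) -> str:
        if stage not in self.stages:
            raise ConfigError(f"unknown stage {stage!r}")
        return self.grouping.get(stage, stage)

    @property
    def analysis_stages(self) -> tuple[str, ...]:
        out: list[str] = []
        for s in self.stages:
            lab = self.grouping.get(s, s)
            if not out or out[-1] != lab:
                out.append(lab)
        return tuple(out)

    def grouped(self) -> "StageScheme":
        """The scheme after applying the grouping (identity grouping left)."""
        return StageScheme(stages=self.analysis_stages)

    def index(self, stage: str) -> int:
        return self.stages.index(stage)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {"stages": list(self.stages), "grouping": dict(self.grouping)}

    @classmethod
    def from_dict(cls, d: dict) -> "StageScheme":
        return cls(stages=tuple(d["stages"]), grouping=dict(d.get("grouping") or {}))


def default_scheme(n_instars: int, group_from: int | None = 5) -> StageScheme:
    """The study's stage scheme: egg, L1..Ln, pupa, adult.

    When ``group_from`` is given and ``n_instars`` exceeds it, the instars
    from ``group_from`` onward are pooled into one analysis stage (named
    e.g. ``"L5-7"``), so that cohorts reared at temperatures inducing
    supernumerary instars share the stage structure of those that do not.
    """
    if n_instars < 1:
        raise ConfigError("need at least one larval instar")
    instars = [f"L{i}" for i in range(1, n_instars + 1)]
    stages = tuple(["egg", *instars, "pupa", "adult"])
    grouping: dict[str, str] = {}
    if group_from is not None and n_instars > group_from:
        pooled = f"L{group_from}-{n_instars}"
        for i in range(group_from, n_instars + 1):
            grouping[f"L{i}"] = pooled
    return StageScheme(stages=stages, grouping=grouping)
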