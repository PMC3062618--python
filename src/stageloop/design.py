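"""Double-loop two-color microarray designs.

A loop design chains samples A -> B -> C -> ... -> A where each arrow is a
single two-channel array co-hybridizing the sample at the arrow's base
(labeled Cy3) with the sample at its head (labeled Cy5).  A *double* loop
traverses the chain in both directions, which balances the dyes: every stage
is measured twice with each dye, on four different arrays, using four
independent biological pools.

For S stages the double loop uses 2*S arrays and 4*S channels, one channel
per biological pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import DesignError

DYES = ("Cy3", "Cy5")

#: deterministic pool-replicate slot for each (loop direction, dye) channel
REPLICATE_SLOTS = {
    ("forward", "Cy3"): 1,
    ("forward", "Cy5"): 2,
    ("reverse", "Cy3"): 3,
    ("reverse", "Cy5"): 4,
}


@dataclass(frozen=True)
class Pool:
    """One biological pool: a replicate of embryos collected at one stage."""

    stage: int
    replicate: int

    @property
    def pool_id(self) -> str:
        return f"S{self.stage}R{self.replicate}"


@dataclass(frozen=True)
class ArrayAssignment:
    """One array: which pool is labeled with which dye."""

    array_id: int
    cy3_pool: Pool
    cy5_pool: Pool


@dataclass
class LoopDesign:
    """A set of two-channel arrays whose (Cy3, Cy5) pools realize a double loop."""

    n_stages: int
    arrays: list[ArrayAssignment] = field(default_factory=list)

    @property
    def n_arrays(self) -> int:
        return len(self.arrays)

    @property
    def channels(self) -> list[tuple[int, str, Pool]]:
        """Flat list of (array_id, dye, pool), two channels per array."""
        out = []
        for arr in self.arrays:
            out.append((arr.array_id, "Cy3", arr.cy3_pool))
            out.append((arr.array_id, "Cy5", arr.cy5_pool))
        return out

    def channel_table(self) -> pd.DataFrame:
        """Channel metadata in the canonical channel order used everywhere."""
        rows = [
            {
                "channel_id": f"A{array_id}_{dye}",
                "array_id": array_id,
                "dye": dye,
                "stage": pool.stage,
                "replicate": pool.replicate,
                "pool_id": pool.pool_id,
            }
            for array_id, dye, pool in self.channels
        ]
        return pd.DataFrame(rows)

    def validate(self) -> None:
        """Assert every structural invariant of a double loop; raise DesignError."""
        S = self.n_stages
        if self.n_arrays != 2 * S:
            raise DesignError(f"expected {2 * S} arrays, found {self.n_arrays}")
        chans = self.channels
        if len(chans) != 4 * S:
            raise DesignError("expected 4 channels per stage")
        pool_ids = [p.pool_id for _, _, p in chans]
        if len(set(pool_ids)) != len(pool_ids):
            raise DesignError("a pool appears in more than one channel")
        # dye balance: every stage hybridized twice with each dye
        counts: dict[tuple[int, str], int] = {}
        for _, dye, pool in chans:
            counts[(pool.stage, dye)] = counts.get((pool.stage, dye), 0) + 1
        for k in range(1, S + 1):
            for dye in DYES:
                if counts.get((k, dye), 0) != 2:
                    raise DesignError(f"stage {k} not dye balanced for {dye}")
        if not self.is_connected():
            raise DesignError("stage co-hybridization graph is disconnected")

    def is_connected(self) -> bool:
        """True if every stage is linked to every other through shared arrays."""
        parent = list(range(self.n_stages + 1))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for arr in self.arrays:
            a, b = find(arr.cy3_pool.stage), find(arr.cy5_pool.stage)
            parent[a] = b
        roots = {find(k) for k in range(1, self.n_stages + 1)}
        return len(roots) == 1


def build_double_loop(n_stages: int) -> LoopDesign:
    """Construct the canonical double loop over ``n_stages`` stages.

    The forward loop is S1 -> S2 -> ... -> SS -> S1 and the reverse loop is
    SS -> SS-1 -> ... -> S1 -> SS, one array per arrow, with the pool at the
    base of each arrow labeled Cy3 and the pool at its head labeled Cy5.
    Replicate pools fill the four channel slots of each stage in a fixed
    order (forward-Cy3 -> rep 1, forward-Cy5 -> rep 2, reverse-Cy3 -> rep 3,
    reverse-Cy5 -> rep 4) so a design is fully reproducible.
    """
    if n_stages < 2:
        raise DesignError("a loop design needs at least 2 stages")
    S = n_stages
    arrays: list[ArrayAssignment] = []
    array_id = 1
    # forward loop: arrow k -> k+1 (wrapping)
    for k in range(1, S + 1):
        head = k % S + 1
        arrays.append(
            ArrayAssignment(
                array_id,
                cy3_pool=Pool(k, REPLICATE_SLOTS[("forward", "Cy3")]),
                cy5_pool=Pool(head, REPLICATE_SLOTS[("forward", "Cy5")]),
            )
        )
        array_id += 1
    # reverse loop: arrow k -> k-1 (wrapping), starting from SS
    for k in range(S, 0, -1):
        head = S if k == 1 else k - 1
        arrays.append(
            ArrayAssignment(
                array_id,
                cy3_pool=Pool(k, REPLICATE_SLOTS[("reverse", "Cy3")]),
                cy5_pool=Pool(head, REPLICATE_SLOTS[("reverse", "Cy5")]),
            )
        )
        array_id += 1
    design = LoopDesign(n_stages=S, arrays=arrays)
    design.validate()
    return design


def design_to_frame(design: LoopDesign) -> pd.DataFrame:
    """Tabular form of the design (one row per array)."""
    return pd.DataFrame(
        [
            {
                "array_id": a.array_id,
                "cy3_stage": a.cy3_pool.stage,
                "cy3_replicate": a.cy3_pool.replicate,
                "cy5_stage": a.cy5_pool.stage,
                "cy5_replicate": a.cy5_pool.replicate,
            }
            for a in design.arrays
        ]
    )


def design_from_frame(frame: pd.DataFrame) -> LoopDesign:
    """Rebuild a LoopDesign from its tabular form (inverse of design_to_frame)."""
    arrays = [
        ArrayAssignment(
            int(r.array_id),
            cy3_pool=Pool(int(r.cy3_stage), int(r.cy3_replicate)),
            cy5_pool=Pool(int(r.cy5_stage), int(r.cy5_replicate)),
        )
        for r in frame.itertuples()
    ]
    n_stages = int(
        max(frame["cy3_stage"].max(), frame["cy5_stage"].max())
    )
    return LoopDesign(n_stages=n_stages, arrays=arrays)
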