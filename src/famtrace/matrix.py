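"""Families x species presence matrices with lineage aggregation.

The matrix is the survey's central product: one three-state cell
(``+`` presence / ``p`` paralog-grade / ``-`` absence, plus ``.`` for
species with no proteome) per family and species, with per-cell copy
counts, and a lineage-level aggregate per family.  A lineage counts as
``present`` when any member species is ``+`` (or ``p``, configurable),
``rescued`` when all core species are negative but a wider-sampling
recheck of extra species in that lineage found a positive, and
``absent`` otherwise.  Wider-sampling calls attach as rescue evidence
only — they never overwrite core cells.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

CELL_STATES = ("+", "p", "-", ".")


class MatrixError(ValueError):
    pass


class PresenceMatrix:
    """Three-state matrix plus copy counts, taxonomy and rescue evidence."""

    def __init__(
        self,
        statuses: pd.DataFrame,
        counts: pd.DataFrame,
        taxonomy: dict[str, str],
        rescues: dict[str, set[str]] | None = None,
    ):
        bad = set(statuses.values.ravel()) - set(CELL_STATES)
        if bad:
            raise MatrixError(f"invalid cell states: {sorted(bad)}")
        if statuses.isnull().values.any():
            raise MatrixError("matrix grid has undefined cells")
        if not statuses.index.equals(counts.index) or not statuses.columns.equals(
            counts.columns
        ):
            raise MatrixError("status and count grids differ in shape")
        missing = set(statuses.columns) - set(taxonomy)
        if missing:
            raise MatrixError(f"species missing from taxonomy: {sorted(missing)}")
        self.statuses = statuses
        self.counts = counts
        self.taxonomy = {sp: taxonomy[sp] for sp in statuses.columns}
        # family -> set of lineages with positive wider-sampling evidence
        self.rescues: dict[str, set[str]] = rescues or {}

    # ------------------------------------------------------------- assembly
    @classmethod
    def assemble(cls, calls: pd.DataFrame, taxonomy: dict[str, str]) -> "PresenceMatrix":
        """Build the matrix from a survey calls table (one row per cell)."""
        required = {"family", "species", "status"}
        if not required <= set(calls.columns):
            raise MatrixError(f"calls table needs columns {sorted(required)}")
        dupes = calls.duplicated(["family", "species"])
        if dupes.any():
            rows = calls[dupes][["family", "species"]].values.tolist()
            raise MatrixError(f"duplicate calls for cells: {rows}")
        statuses = calls.pivot(index="family", columns="species", values="status")
        if statuses.isnull().values.any():
            holes = [
                (f, s)
                for f in statuses.index
                for s in statuses.columns
                if pd.isnull(statuses.loc[f, s])
            ]
            raise MatrixError(f"missing calls for cells: {holes}")
        if "n_candidates" in calls.columns:
            counts = calls.pivot(
                index="family", columns="species", values="n_candidates"
            ).astype(int)
        else:
            counts = statuses.isin(["+", "p"]).astype(int)
        statuses = statuses.sort_index()
        counts = counts.sort_index().loc[statuses.index, statuses.columns]
        return cls(statuses, counts, taxonomy)

    def to_calls(self) -> pd.DataFrame:
        """Inverse of :meth:`assemble` (lossless for status and count)."""
        rows = [
            {
                "family": fam,
                "species": sp,
                "status": self.statuses.loc[fam, sp],
                "n_candidates": int(self.counts.loc[fam, sp]),
            }
            for fam in self.statuses.index
            for sp in self.statuses.columns
        ]
        return pd.DataFrame(rows)

    @property
    def families(self) -> list[str]:
        return list(self.statuses.index)

    @property
    def species(self) -> list[str]:
        return list(self.statuses.columns)

    @property
    def lineages(self) -> list[str]:
        return list(dict.fromkeys(self.taxonomy.values()))

    def cell(self, family: str, species: str) -> str:
        return self.statuses.loc[family, species]

    # ---------------------------------------------------------- aggregation
    def aggregate_lineage(
        self, family: str, paralog_counts: bool = True
    ) -> dict[str, str]:
        """Per-lineage status for one family: present / rescued / absent.

        ``paralog_counts`` controls whether paralog-grade (``p``) cells
        fill a lineage's sector; the default mirrors the survey matrix
        (blue cells still fill the sector).
        """
        positive = ("+", "p") if paralog_counts else ("+",)
        out: dict[str, str] = {}
        for lin in self.lineages:
            members = [sp for sp in self.species if self.taxonomy[sp] == lin]
            if any(self.statuses.loc[family, sp] in positive for sp in members):
                out[lin] = "present"
            elif lin in self.rescues.get(family, set()):
                out[lin] = "rescued"
            else:
                out[lin] = "absent"
        return out

    def aggregate_all(self, paralog_counts: bool = True) -> pd.DataFrame:
        recs = {
            fam: self.aggregate_lineage(fam, paralog_counts) for fam in self.families
        }
        return pd.DataFrame(recs).T.loc[self.families, self.lineages]

    # -------------------------------------------------------- wider sampling
    def extend_sampling(
        self, family: str, extra_calls: pd.DataFrame, extra_taxonomy: dict[str, str]
    ) -> "PresenceMatrix":
        """Attach wider-sampling calls for extra (non-core) species.

        Positive extra calls mark their lineage as rescue evidence for the
        family.  An extra call for a core species is rejected; core cells
        are never overwritten.  Returns self (mutated in place).
        """
        if family not in self.statuses.index:
            raise MatrixError(f"unknown family {family!r}")
        for row in extra_calls.itertuples():
            if row.species in self.statuses.columns:
                raise MatrixError(
                    f"wider-sampling call for core species {row.species!r} rejected"
                )
            if row.species not in extra_taxonomy:
                raise MatrixError(f"extra species {row.species!r} has no lineage")
            if row.status in ("+", "p"):
                self.rescues.setdefault(family, set()).add(
                    extra_taxonomy[row.species]
                )
        return self

    # ----------------------------------------------------------------- I/O
    def to_tsv(self, path: str | Path) -> None:
        """Write the grid; presence cells with >1 copy render as '+2' etc."""
        with open(path, "w") as fh:
            fh.write("family\t" + "\t".join(self.species) + "\n")
            fh.write("#lineage\t" + "\t".join(self.taxonomy[s] for s in self.species) + "\n")
            for fam in self.families:
                cells = []
                for sp in self.species:
                    st = self.statuses.loc[fam, sp]
                    n = int(self.counts.loc[fam, sp])
                    cells.append(f"{st}{n}" if st in ("+", "p") and n > 1 else st)
                fh.write(fam + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceMatrix":
        lines = Path(path).read_text().splitlines()
        header = lines[0].split("\t")
        species = header[1:]
        lin_row = lines[1].split("\t")
        if lin_row[0] != "#lineage":
            raise MatrixError("expected '#lineage' row after the header")
        taxonomy = dict(zip(species, lin_row[1:]))
        fams, stat_rows, count_rows = [], [], []
        for line in lines[2:]:
            if not line.strip():
                continue
            parts = line.split("\t")
            fams.append(parts[0])
            srow, crow = [], []
            for cell in parts[1:]:
                state = cell[0]
                n = int(cell[1:]) if len(cell) > 1 else (1 if state in "+p" else 0)
                srow.append(state)
                crow.append(n)
            stat_rows.append(srow)
            count_rows.append(crow)
        statuses = pd.DataFrame(stat_rows, index=fams, columns=species)
        counts = pd.DataFrame(count_rows, index=fams, columns=species)
        return cls(statuses, counts, taxonomy)

    def lineage_tsv(self, path: str | Path, paralog_counts: bool = True) -> None:
        self.aggregate_all(paralog_counts).to_csv(path, sep="\t", index_label="family")

    def equals(self, other: "PresenceMatrix") -> bool:
        return (
            self.statuses.equals(other.statuses)
            and self.counts.equals(other.counts)
            and self.taxonomy == other.taxonomy
        )

    # ----------------------------------------------------------------- plot
    def plot(self, path: str | Path) -> None:
        """Figure-style grid: filled = present, hatched = paralog-grade."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import numpy as np

        code = {"+": 2.0, "p": 1.0, "-": 0.0, ".": np.nan}
        grid = self.statuses.map(lambda s: code[s]).values.astype(float)
        fig, ax = plt.subplots(
            figsize=(max(4, 0.3 * len(self.species)), max(3, 0.3 * len(self.families)))
        )
        ax.imshow(grid, cmap="Greens", vmin=0, vmax=2, aspect="auto")
        ax.set_xticks(range(len(self.species)))
        ax.set_xticklabels(self.species, rotation=90, fontsize=6)
        ax.set_yticks(range(len(self.families)))
        ax.set_yticklabels(self.families, fontsize=6)
        ax.set_title("family presence across species")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
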