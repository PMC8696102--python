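"""Alignment accuracy measures and performance profiles.

Q_C is the fraction of reference columns whose complete structure→residue
mapping is reproduced inside a single test column (the stringent measure);
Q_P is the fraction of reference-induced aligned residue pairs reproduced
by the test alignment (the lenient one).  Per-case accuracies across
methods are aggregated into Dolan–Moré performance profiles
ρ_m(α) = |{a : r_{m,a} ≥ α}| / |A| with r_{m,a} = c_{m,a} / max_m c_{m,a}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .multialign import MultipleAlignment
from .structure import Structure

log = logging.getLogger(__name__)


def _check_same_structures(test: MultipleAlignment, ref: MultipleAlignment) -> None:
    if len(test.structures) != len(ref.structures):
        raise ValueError("structure sets differ")
    names_t = {s.name for s in test.structures}
    names_r = {s.name for s in ref.structures}
    if names_t != names_r:
        raise ValueError(f"structure sets differ: {names_t} vs {names_r}")


def _index_map(test: MultipleAlignment, ref: MultipleAlignment) -> dict[int, int]:
    """Map ref structure index -> test structure index by name."""
    by_name = {s.name: i for i, s in enumerate(test.structures)}
    return {i: by_name[s.name] for i, s in enumerate(ref.structures)}


def qc(test: MultipleAlignment, ref: MultipleAlignment) -> float:
    """Percent of reference columns fully contained in some test column."""
    _check_same_structures(test, ref)
    remap = _index_map(test, ref)
    r2c = test.residue_to_column()
    correct = 0
    for col in ref.columns:
        items = [(remap[s], r) for s, r in col.items()]
        cols = {r2c.get(it) for it in items}
        if len(cols) == 1 and None not in cols:
            correct += 1
    return 100.0 * correct / len(ref.columns) if ref.columns else 0.0


def qp(test: MultipleAlignment, ref: MultipleAlignment) -> float:
    """Percent of reference-induced aligned residue pairs reproduced."""
    _check_same_structures(test, ref)
    remap = _index_map(test, ref)
    ref_pairs = {
        tuple(sorted(((remap[a[0]], a[1]), (remap[b[0]], b[1]))))
        for a, b in ref.aligned_pairs()
    }
    test_pairs = {tuple(sorted(p)) for p in test.aligned_pairs()}
    if not ref_pairs:
        return 0.0
    return 100.0 * len(ref_pairs & test_pairs) / len(ref_pairs)


@dataclass(frozen=True)
class AccuracyRecord:
    method: str
    case: str
    qc: float
    qp: float
    failed: bool = False


def records_frame(records: list[AccuracyRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records])
    df.loc[df["failed"], ["qc", "qp"]] = 0.0
    return df


def accuracy_ratio(records: list[AccuracyRecord], measure: str = "qc") -> pd.DataFrame:
    """Per-case accuracy divided by the best accuracy over methods.

    Cases where every method scores 0 get ratio 0 (with a warning).
    Returns a DataFrame with columns method, case, ratio.
    """
    df = records_frame(records)
    best = df.groupby("case")[measure].transform("max")
    ratio = np.where(best > 0, df[measure] / best.replace(0, np.nan), 0.0)
    if (best == 0).any():
        log.warning("cases with all-zero accuracy: %s", sorted(df.loc[best == 0, "case"].unique()))
    out = df[["method", "case"]].copy()
    out["ratio"] = np.nan_to_num(ratio)
    return out


@dataclass
class Profile:
    method: str
    alphas: np.ndarray
    rho: np.ndarray

    @property
    def auc(self) -> float:
        return float(np.trapezoid(self.rho, self.alphas))


def performance_profile(
    ratios: pd.DataFrame, alphas: np.ndarray | None = None
) -> dict[str, Profile]:
    """ρ_m(α): fraction of cases where method m is within ratio α of the
    per-case best.  Non-increasing, right-continuous step functions.

    Failed cases carry ratio 0 and never count, so ρ_m(0) equals the
    fraction of cases the method actually solved.
    """
    if alphas is None:
        alphas = np.arange(0.0, 1.0 + 1e-9, 0.01)
    cases = ratios["case"].unique()
    out: dict[str, Profile] = {}
    for method, sub in ratios.groupby("method"):
        r = sub.set_index("case")["ratio"].reindex(cases).fillna(0.0).to_numpy()
        rho = np.array([(r >= max(a, 1e-12)).mean() for a in alphas])
        out[method] = Profile(str(method), alphas.copy(), rho)
    return out


def profiles_to_tsv(profiles: dict[str, Profile]) -> str:
    lines = ["method\talpha\trho"]
    for m in sorted(profiles):
        p = profiles[m]
        for a, r in zip(p.alphas, p.rho):
            lines.append(f"{m}\t{a:.2f}\t{r:.4f}")
    return "\n".join(lines) + "\n"


def plot_profiles(profiles: dict[str, Profile], path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for m in sorted(profiles):
        p = profiles[m]
        ax.step(p.alphas, p.rho, where="post", label=f"{m} (AUC {p.auc:.2f})")
    ax.set_xlabel(r"$\alpha$")
    ax.set_ylabel(r"$\rho_m(\alpha)$")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def read_reference_fasta(path: str | Path, structures: list[Structure]) -> MultipleAlignment:
    """Read a reference multiple alignment from FASTA (gap '-').

    Record names must match structure names; the k-th non-gap character of
    a record corresponds to the structure's k-th residue.
    """
    text = Path(path).read_text()
    seqs: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name is not None:
            seqs[name] += line
    by_name = {s.name: i for i, s in enumerate(structures)}
    missing = set(seqs) - set(by_name)
    if missing:
        raise ValueError(f"alignment records without structures: {sorted(missing)}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("alignment records have unequal lengths")
    counters = {n: 0 for n in seqs}
    columns: list[dict[int, int]] = []
    for k in range(lengths.pop()):
        col: dict[int, int] = {}
        for n, seq in seqs.items():
            ch = seq[k]
            if ch != "-":
                col[by_name[n]] = counters[n]
                counters[n] += 1
        if col:
            columns.append(col)
    return MultipleAlignment(structures, columns)
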