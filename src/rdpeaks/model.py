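"""Model/Results interface to the peak caller.

:class:`RnaDnaPeakModel` holds the data (contacts, chromosome sizes, gene
annotation, background) and configuration; :meth:`RnaDnaPeakModel.fit` runs
binning, background rebinning, distance-decay estimation and binomial
testing per RNA, pools the dual multiple-testing correction, and returns a
:class:`PeakCallingResults` carrying the per-bin table, diagnostics, a
``summary()`` and exporters (narrowPeak, HDF5 container, scaling TSV).

The three algorithm stages are also exposed as free functions operating on
per-RNA state dicts (:func:`stage_bins`, :func:`stage_background`,
:func:`stage_scaling`, :func:`stage_pvalues`) so they can be run and
persisted one at a time from the command line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import background as bg_mod
from . import binning, io, peak_calling, scaling

logger = logging.getLogger(__name__)

STAGES = ("bins", "background", "scaling", "pvals")


@dataclass(frozen=True)
class BinningParams:
    """Bin-size search and cis-growth parameters (bp).

    Defaults suit all-to-all data; for high-resolution one-to-all data use
    ``BinningParams.ota()`` (trans_min 400, trans_step 50, cis_start 100).
    ``cis_start=None`` derives startsize as trans_binsize/10 rounded to a
    multiple of 10.
    """

    trans_min: int = 10_000
    trans_max: int = 1_000_000
    trans_step: int = 1_000
    cis_start: int | None = None
    # gentle growth keeps bins fine across the whole distance-decay zone
    # (width roughly tracking the reciprocal decay = even expected coverage)
    cis_factor: float = 1.05

    @classmethod
    def ota(cls, **kw) -> "BinningParams":
        return cls(**{"trans_min": 400, "trans_step": 50, "cis_start": 100, **kw})

    def startsize_for(self, trans_binsize: int) -> int:
        if self.cis_start is not None:
            return int(self.cis_start)
        return max(10, int(round(trans_binsize / 10 / 10)) * 10)


class RnaDnaPeakModel:
    """Binomial background model for RNA-DNA contact data.

    Parameters
    ----------
    contacts : DataFrame with columns chrom/start/end/rna_name (DNA parts of
        contacts, BED convention).
    chromsizes : mapping chromosome name -> length (bp).
    annotation : mapping gene name -> :class:`rdpeaks.io.GeneRecord`; must
        cover every RNA to be tested.
    background : :class:`rdpeaks.io.FineTrack`, or None to build the pooled
        mRNA-trans background from the data (all-to-all mode).
    mrna_names : explicit background gene list for the mRNA mode; default is
        all protein-coding genes in the annotation.
    bg_binsize : fine background resolution (bp, default 1000).
    binning_params : :class:`BinningParams`.
    min_contacts : keep RNAs with strictly more contacts than this (default
        1000).
    """

    def __init__(
        self,
        contacts: pd.DataFrame,
        chromsizes: dict[str, int],
        annotation: dict[str, io.GeneRecord],
        background: io.FineTrack | None = None,
        *,
        mrna_names: list[str] | None = None,
        bg_binsize: int = 1000,
        binning_params: BinningParams | None = None,
        min_contacts: int = peak_calling.DEFAULT_MIN_CONTACTS,
    ):
        io.validate_contacts(contacts, chromsizes)
        self.contacts = contacts
        self.chromsizes = dict(chromsizes)
        self.annotation = dict(annotation)
        self.bg_binsize = int(bg_binsize)
        self.binning_params = binning_params or BinningParams()
        self.min_contacts = int(min_contacts)
        selected = peak_calling.filter_rnas(contacts, min_contacts)
        self.rnas = [r for r in selected if r in self.annotation]
        skipped = sorted(set(selected) - set(self.rnas))
        if skipped:
            logger.warning(
                "%d RNAs above the contact threshold lack annotation: %s",
                len(skipped), skipped[:5],
            )
        if background is None:
            names = mrna_names or bg_mod.select_mrnas(self.annotation)
            background = bg_mod.build_ata_background(
                contacts, self.annotation, names, self.chromsizes, self.bg_binsize
            )
            self.background_source = "mrna_trans"
        else:
            self.background_source = "custom"
        self.background = background

    @classmethod
    def from_files(
        cls,
        contacts_path,
        chromsizes_path,
        annotation_path,
        bedgraph_path=None,
        mrna_list_path=None,
        **kwargs,
    ) -> "RnaDnaPeakModel":
        """Build the model from the four standard input files."""
        chromsizes = io.read_chromsizes(chromsizes_path)
        contacts = io.read_contacts(contacts_path, chromsizes)
        annotation = io.read_annotation(annotation_path)
        track = None
        if bedgraph_path is not None:
            track = io.read_bedgraph(bedgraph_path, chromsizes)
        mrna_names = None
        if mrna_list_path is not None:
            with open(mrna_list_path) as fh:
                mrna_names = [ln.strip() for ln in fh if ln.strip()]
        return cls(
            contacts, chromsizes, annotation, track, mrna_names=mrna_names, **kwargs
        )

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        *,
        no_scaling: bool = False,
        no_background: bool = False,
        alpha_refine: float = 0.05,
        scaling_smooth: float | None = None,
        n_jobs: int = 1,
    ) -> "PeakCallingResults":
        """Run the full pipeline and return results.

        ``no_scaling`` fixes all distance-decay factors to 1;
        ``no_background`` replaces the heterogeneity track with a uniform
        one. A failure on one RNA quarantines it and the fit continues.
        """
        if not self.rnas:
            raise ValueError(
                f"no RNA exceeds {self.min_contacts} contacts with annotation present"
            )
        by_rna = dict(tuple(self.contacts.groupby("rna_name", sort=False, observed=True)))

        def _one(rna: str):
            try:
                return rna, self._fit_single_rna(
                    rna, by_rna[rna],
                    no_scaling=no_scaling,
                    no_background=no_background,
                    alpha_refine=alpha_refine,
                    scaling_smooth=scaling_smooth,
                ), None
            except Exception as exc:  # quarantine, keep going
                logger.exception("RNA %s failed", rna)
                return rna, None, str(exc)

        if n_jobs == 1:
            outcomes = [_one(r) for r in self.rnas]
        else:
            outcomes = Parallel(n_jobs=n_jobs, prefer="threads")(
                delayed(_one)(r) for r in self.rnas
            )
        fits: dict[str, RnaFit] = {}
        quarantined: dict[str, str] = {}
        for rna, fit, err in outcomes:
            if fit is None:
                quarantined[rna] = err
            else:
                fits[rna] = fit
        if quarantined:
            logger.warning("quarantined RNAs: %s", sorted(quarantined))
        results = PeakCallingResults(
            model=self, fits=fits, quarantined=quarantined,
            options={
                "no_scaling": no_scaling, "no_background": no_background,
                "alpha_refine": alpha_refine,
            },
        )
        results._apply_dual_correction()
        return results

    def _fit_single_rna(
        self, rna, contacts, *, no_scaling, no_background, alpha_refine, scaling_smooth
    ) -> "RnaFit":
        state = {"rna_name": rna}
        stage_bins(state, contacts, self.annotation[rna], self.chromsizes,
                   self.binning_params)
        stage_background(
            state,
            background=None if no_background else self.background,
        )
        stage_scaling(state, no_scaling=no_scaling, alpha_refine=alpha_refine,
                      smooth=scaling_smooth)
        stage_pvalues(state)
        return RnaFit.from_state(state)


# ---------------------------------------------------------------------------
# stage functions (shared by fit() and the staged command-line flow)


def stage_bins(
    state: dict,
    contacts: pd.DataFrame,
    gene: io.GeneRecord,
    chromsizes: dict[str, int],
    params: BinningParams,
) -> dict:
    """Stage 1: choose the trans bin size, build the grid, count contacts."""
    trans_binsize = binning.select_trans_binsize(
        contacts, chromsizes, gene.chrom,
        params.trans_min, params.trans_max, params.trans_step,
    )
    startsize = params.startsize_for(trans_binsize)
    grid = binning.build_grid(
        gene, chromsizes, startsize, params.cis_factor, trans_binsize,
        rna_name=state["rna_name"],
    )
    counted = binning.count_in_bins(contacts, grid)
    gene_body = grid.table["is_gene_body"].to_numpy(bool)
    is_cis = grid.table["is_cis"].to_numpy(bool)
    counts = counted.counts
    state.update(
        grid=grid,
        counts=counts,
        n_rejected=counted.n_rejected,
        n_total=int(counts[~gene_body].sum()),
        n_cis=int(counts[is_cis & ~gene_body].sum()),
        n_trans=int(counts[~is_cis].sum()),
        trans_binsize=int(trans_binsize),
        startsize=int(startsize),
        factor=float(params.cis_factor),
    )
    state["stage"] = "bins"
    return state


def stage_background(state: dict, background: io.FineTrack | None) -> dict:
    """Stage 2: rebin the heterogeneity track (or uniform) onto the grid."""
    grid: binning.BinGrid = state["grid"]
    testable = ~grid.table["is_gene_body"].to_numpy(bool)
    if background is None:
        rebinned = bg_mod.uniform_background(grid)
        prob = bg_mod.bg_probabilities(rebinned, testable)
    else:
        rebinned = bg_mod.rebin_background(background, grid)
        prob = bg_mod.bg_probabilities(
            rebinned, testable,
            widths=grid.widths,
            min_nonzero_fine=background.min_nonzero(),
            fine_binsize=background.binsize,
        )
    state.update(bg_counts=rebinned, bg_prob=prob, testable=testable)
    state["stage"] = "background"
    return state


def stage_scaling(
    state: dict,
    *,
    no_scaling: bool = False,
    alpha_refine: float = 0.05,
    smooth: float | None = None,
) -> dict:
    """Stage 3: estimate the per-RNA distance-decay factor on cis bins."""
    grid: binning.BinGrid = state["grid"]
    table = grid.table
    cis = table["is_cis"].to_numpy(bool) & ~table["is_gene_body"].to_numpy(bool)
    factors = np.ones(len(table))
    if no_scaling or state["n_total"] == 0:
        flat = scaling.ScalingModel(rna_name=state["rna_name"])
        model1 = model2 = flat
    else:
        model1, model2 = scaling.estimate_scaling(
            state["counts"][cis],
            state["n_total"],
            state["bg_prob"][cis],
            table["distance"].to_numpy()[cis],
            cis_mass=state["n_cis"] / state["n_total"] if state["n_total"] else 0.0,
            alpha_refine=alpha_refine,
            smooth=smooth,
            rna_name=state["rna_name"],
        )
        factors[cis] = model2(table["distance"].to_numpy()[cis])
    state.update(scaling_factor=factors, scaling_model=model2, scaling_step1=model1)
    state["stage"] = "scaling"
    return state


def stage_pvalues(state: dict) -> dict:
    """Stage 4: assemble p_ij and compute right-sided binomial p-values."""
    grid: binning.BinGrid = state["grid"]
    table = grid.table
    is_cis = table["is_cis"].to_numpy(bool)
    testable = state["testable"]
    probs = peak_calling.assemble_probs(
        state["bg_prob"], state["scaling_factor"], is_cis, testable,
        state["n_cis"], state["n_trans"],
    )
    counts = state["counts"]
    pvalue = np.full(len(table), np.nan)
    tested = testable & (probs > 0)
    pvalue[tested] = peak_calling.binom_right_pvalue(
        counts[tested], state["n_total"], probs[tested]
    )
    state.update(probs=probs, pvalue=pvalue, tested=tested)
    state["stage"] = "pvals"
    return state


# -- container round-trip for the staged command-line flow -----------------

_STAGE_ARRAYS = {
    "bins": ["counts"],
    "background": ["bg_counts", "bg_prob"],
    "scaling": ["scaling_factor"],
    "pvals": ["probs", "pvalue", "qvalue_global", "qvalue_rna"],
}
_ARRAY_NAMES = {  # state key -> container dataset name
    "counts": "count", "bg_counts": "bg_count", "bg_prob": "bg_prob",
    "scaling_factor": "scaling", "probs": "prob", "pvalue": "pvalue",
    "qvalue_global": "qvalue_global", "qvalue_rna": "qvalue_rna",
}


def payload_from_state(state: dict) -> dict:
    """Serialize a per-RNA state dict for :func:`rdpeaks.io.store_dataset`."""
    grid: binning.BinGrid = state["grid"]
    t = grid.table
    arrays = {
        "chrom": t["chrom"].to_numpy(object),
        "bin_start": t["start"].to_numpy(np.int64),
        "bin_end": t["end"].to_numpy(np.int64),
        "is_cis": t["is_cis"].to_numpy(bool),
        "is_gene_body": t["is_gene_body"].to_numpy(bool),
        "distance": t["distance"].to_numpy(float),
    }
    stage = state.get("stage", "bins")
    for st in STAGES[: STAGES.index(stage) + 1]:
        for key in _STAGE_ARRAYS[st]:
            if key in state and state[key] is not None:
                arrays[_ARRAY_NAMES[key]] = np.asarray(state[key])
    attrs = {
        "N": state["n_total"], "N_cis": state["n_cis"], "N_trans": state["n_trans"],
        "n_rejected": state.get("n_rejected", 0),
        "trans_binsize": state["trans_binsize"],
        "startsize": state["startsize"], "factor": state["factor"],
        "gene_chrom": grid.gene.chrom,
        "gene_start": grid.gene.start, "gene_end": grid.gene.end,
        "stage": stage,
    }
    return {"attrs": attrs, "arrays": arrays}


def state_from_payload(rna: str, payload: dict, chromsizes: dict[str, int]) -> dict:
    """Rebuild the in-memory per-RNA state from a loaded container group."""
    attrs, arrays = payload["attrs"], payload["arrays"]
    table = pd.DataFrame(
        {
            "chrom": arrays["chrom"],
            "start": arrays["bin_start"],
            "end": arrays["bin_end"],
            "is_cis": arrays["is_cis"].astype(bool),
            "is_gene_body": arrays["is_gene_body"].astype(bool),
            "distance": arrays["distance"],
        }
    )
    gene = io.GeneRecord(
        str(attrs["gene_chrom"]), int(attrs["gene_start"]), int(attrs["gene_end"]), rna
    )
    grid = binning.BinGrid(
        table=table, rna_name=rna, gene=gene,
        trans_binsize=int(attrs["trans_binsize"]),
        startsize=int(attrs["startsize"]), factor=float(attrs["factor"]),
        chromsizes=dict(chromsizes),
    )
    state = {
        "rna_name": rna, "grid": grid, "stage": str(attrs["stage"]),
        "n_total": int(attrs["N"]), "n_cis": int(attrs["N_cis"]),
        "n_trans": int(attrs["N_trans"]),
        "n_rejected": int(attrs.get("n_rejected", 0)),
        "trans_binsize": int(attrs["trans_binsize"]),
        "startsize": int(attrs["startsize"]), "factor": float(attrs["factor"]),
        "testable": ~table["is_gene_body"].to_numpy(bool),
    }
    for key, name in _ARRAY_NAMES.items():
        if name in arrays:
            state[key] = arrays[name]
    if "counts" in state:
        state["counts"] = np.asarray(state["counts"], np.int64)
    return state


def require_stage(state: dict, needed: str, command: str) -> None:
    """Staged commands consume the previous stage's container in order."""
    have = state.get("stage", "")
    if have not in STAGES or STAGES.index(have) < STAGES.index(needed):
        raise ValueError(
            f"'{command}' needs a container at stage {needed!r} "
            f"(found {have!r}); run 'rdpeaks {needed}' first"
        )


@dataclass
class RnaFit:
    """Frozen per-RNA fit: grid, counts, probabilities, scaling, p-values."""

    rna_name: str
    grid: binning.BinGrid
    counts: np.ndarray
    bg_counts: np.ndarray
    bg_prob: np.ndarray
    scaling_factor: np.ndarray
    probs: np.ndarray
    pvalue: np.ndarray
    tested: np.ndarray
    n_total: int
    n_cis: int
    n_trans: int
    n_rejected: int
    trans_binsize: int
    startsize: int
    factor: float
    scaling_model: scaling.ScalingModel | None = None
    scaling_step1: scaling.ScalingModel | None = None
    qvalue_global: np.ndarray | None = None
    qvalue_rna: np.ndarray | None = None

    @classmethod
    def from_state(cls, state: dict) -> "RnaFit":
        keys = [
            "rna_name", "grid", "counts", "bg_counts", "bg_prob",
            "scaling_factor", "probs", "pvalue", "tested", "n_total",
            "n_cis", "n_trans", "n_rejected", "trans_binsize", "startsize",
            "factor", "scaling_model", "scaling_step1",
        ]
        return cls(**{k: state[k] for k in keys})


class PeakCallingResults:
    """Fit results: per-bin statistics, q-values, exporters, diagnostics."""

    def __init__(self, model, fits: dict[str, RnaFit], quarantined=None, options=None):
        self.model = model
        self.fits = fits
        self.quarantined = quarantined or {}
        self.options = options or {}
        self._table: pd.DataFrame | None = None

    def _apply_dual_correction(self) -> None:
        """Pool non-empty tested bins over RNAs; BH globally and per RNA."""
        pvals, rnas, index = [], [], []
        for rna, fit in self.fits.items():
            sel = fit.tested & (fit.counts > 0)
            pvals.append(fit.pvalue[sel])
            rnas.append(np.full(int(sel.sum()), rna, object))
            index.append(np.nonzero(sel)[0])
        if not pvals:
            return
        pvals_all = np.concatenate(pvals)
        rnas_all = np.concatenate(rnas)
        qg, qr = peak_calling.correct_dual(pvals_all, rnas_all)
        offset = 0
        for rna, fit in self.fits.items():
            idx = index.pop(0)
            n = len(idx)
            fit.qvalue_global = np.full(len(fit.counts), np.nan)
            fit.qvalue_rna = np.full(len(fit.counts), np.nan)
            fit.qvalue_global[idx] = qg[offset:offset + n]
            fit.qvalue_rna[idx] = qr[offset:offset + n]
            offset += n

    @property
    def table(self) -> pd.DataFrame:
        """One row per (RNA, bin) with counts, probabilities and q-values."""
        if self._table is None:
            frames = []
            for rna, fit in self.fits.items():
                t = fit.grid.table.copy()
                t["rna_name"] = rna
                t["count"] = fit.counts
                t["bg_prob"] = fit.bg_prob
                t["scaling"] = fit.scaling_factor
                t["prob"] = fit.probs
                t["pvalue"] = fit.pvalue
                t["qvalue_global"] = fit.qvalue_global
                t["qvalue_rna"] = fit.qvalue_rna
                with np.errstate(divide="ignore", invalid="ignore"):
                    expected = fit.n_total * fit.probs
                    t["fold"] = np.where(expected > 0, fit.counts / expected, np.nan)
                t["N"] = fit.n_total
                frames.append(t)
            self._table = pd.concat(frames, ignore_index=True)
        return self._table

    def peaks(
        self,
        q_threshold: float = peak_calling.DEFAULT_QVALUE,
        mode: str = "global",
        merge: bool = False,
    ) -> pd.DataFrame:
        out = peak_calling.call_peaks(self.table, q_threshold, mode)
        if merge:
            out = peak_calling.merge_adjacent(out)
        return out

    def to_narrowpeak(self, path, q_threshold: float = peak_calling.DEFAULT_QVALUE,
                      mode: str = "global", merge: bool = False) -> pd.DataFrame:
        return io.write_narrowpeak(self.peaks(q_threshold, mode, merge), path,
                                   q_threshold=np.inf)

    # -- persistence -------------------------------------------------------

    def to_state(self) -> dict:
        rnas = {}
        for rna, fit in self.fits.items():
            t = fit.grid.table
            rnas[rna] = {
                "attrs": {
                    "N": fit.n_total, "N_cis": fit.n_cis, "N_trans": fit.n_trans,
                    "n_rejected": fit.n_rejected,
                    "trans_binsize": fit.trans_binsize,
                    "startsize": fit.startsize, "factor": fit.factor,
                    "gene_chrom": fit.grid.gene.chrom,
                    "gene_start": fit.grid.gene.start,
                    "gene_end": fit.grid.gene.end,
                },
                "arrays": {
                    "chrom": t["chrom"].to_numpy(object),
                    "bin_start": t["start"].to_numpy(np.int64),
                    "bin_end": t["end"].to_numpy(np.int64),
                    "is_cis": t["is_cis"].to_numpy(bool),
                    "is_gene_body": t["is_gene_body"].to_numpy(bool),
                    "distance": t["distance"].to_numpy(float),
                    "count": fit.counts,
                    "bg_count": fit.bg_counts,
                    "bg_prob": fit.bg_prob,
                    "scaling": fit.scaling_factor,
                    "prob": fit.probs,
                    "pvalue": fit.pvalue,
                    "qvalue_global": np.asarray(fit.qvalue_global, float),
                    "qvalue_rna": np.asarray(fit.qvalue_rna, float),
                },
            }
        return {
            "meta": {
                "stage": "pvals",
                **{k: str(v) for k, v in self.options.items()},
            },
            "chromsizes": self.model.chromsizes,
            "rnas": rnas,
        }

    def save(self, path) -> None:
        io.store_dataset(self.to_state(), path)

    # -- diagnostics -------------------------------------------------------

    def scaling_table(self, rna: str) -> pd.DataFrame:
        """Diagnostic (d, raw factor, step-1 fit, step-2 fit) for one RNA."""
        fit = self.fits[rna]
        t = fit.grid.table
        cis = t["is_cis"].to_numpy(bool) & ~t["is_gene_body"].to_numpy(bool)
        d = t["distance"].to_numpy()[cis]
        if fit.n_total > 0:
            _, fhat, _ = scaling.raw_scaling_points(
                fit.counts[cis], fit.n_total, fit.bg_prob[cis], d
            )
        else:
            fhat = np.zeros(cis.sum())
        return pd.DataFrame(
            {
                "distance": d,
                "f_raw": fhat,
                "f_fit_step1": fit.scaling_step1(d) if fit.scaling_step1 else 1.0,
                "f_fit_step2": fit.scaling_model(d) if fit.scaling_model else 1.0,
            }
        )

    def plot_scaling(self, rna: str, ax=None):
        """Log-log plot of raw and fitted scaling factors for one RNA."""
        import matplotlib.pyplot as plt

        diag = self.scaling_table(rna)
        if ax is None:
            _, ax = plt.subplots()
        ax.loglog(diag["distance"], diag["f_raw"], ".", ms=2, alpha=0.4, label="raw")
        ax.loglog(diag["distance"], diag["f_fit_step1"], label="step 1")
        ax.loglog(diag["distance"], diag["f_fit_step2"], label="step 2")
        ax.set_xlabel("distance from gene (bp)")
        ax.set_ylabel("scaling factor f(d)")
        ax.set_title(rna)
        ax.legend()
        return ax

    def summary(self, q_threshold: float = peak_calling.DEFAULT_QVALUE) -> str:
        """Plain-text per-RNA fit summary."""
        rows = []
        peaks = self.peaks(q_threshold)
        for rna, fit in self.fits.items():
            rows.append(
                {
                    "rna": rna,
                    "contacts": fit.n_total,
                    "cis_frac": round(fit.n_cis / fit.n_total, 3) if fit.n_total else np.nan,
                    "trans_bin": fit.trans_binsize,
                    "bins": len(fit.counts),
                    "tested": int((fit.tested & (fit.counts > 0)).sum()),
                    "peaks": int((peaks["rna_name"] == rna).sum()),
                }
            )
        df = pd.DataFrame(rows)
        lines = [
            "RNA-DNA interaction peak calling",
            "=" * 64,
            f"RNAs fitted: {len(self.fits)}"
            + (f" (quarantined: {len(self.quarantined)})" if self.quarantined else ""),
            f"options: {self.options}",
            f"peaks at global q < {q_threshold}: {len(peaks)}",
            "-" * 64,
            df.to_string(index=False),
        ]
        return "\n".join(lines)
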