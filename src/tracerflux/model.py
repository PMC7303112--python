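"""Model/Results interface for the tracer-flux carbon-budget analysis.

:class:`TracerBudgetModel` is built from the validated input tables
(specimens, substrate batches, incubations, O2 series, optionally the
food-chain table); :meth:`TracerBudgetModel.fit` estimates, per animal,
the control-corrected total-C fluxes (respiration from the O2 regression,
POC and DOC release from start/end concentration pairs), the tracer-C
fluxes (from the excess-13C inventory change of the DIC and POC pools),
and the tissue tracer-C incorporation, standardizes everything to tissue
organic carbon, and assembles the per-animal budget.  The returned
:class:`TracerBudgetResults` carries the budget table, chamber-level flux
estimates and diagnostics, group summaries, the nonparametric test
battery, and the food-chain transfer efficiency.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import budget as bud
from . import flux as flx
from . import stats as nps
from .errors import MissingBackgroundError, TracerFluxError
from .io import Dataset, PipelineConfig, read_tables, write_table
from .isotopes import delta_to_atom_fraction
from .simulate import SimulatedDataset, food_chain_record
from .tissue import Specimen, incorporation_rate, percent_of_provided, sponge_oc_from_volume

_POOL_QUANTITY = {"poc": "poc_total", "doc": "doc_total"}


def _opt(row, key):
    v = row.get(key)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return v


class TracerBudgetModel:
    """Carbon-budget model over one tracer experiment's tables."""

    def __init__(self, dataset: Dataset, config: PipelineConfig | None = None):
        self.dataset = dataset
        self.config = config or PipelineConfig()

    @classmethod
    def from_csv(
        cls,
        specimens,
        batches,
        incubations,
        o2_series,
        foodchain=None,
        config: PipelineConfig | None = None,
    ) -> "TracerBudgetModel":
        return cls(read_tables(specimens, batches, incubations, o2_series, foodchain), config)

    @classmethod
    def from_simulation(
        cls,
        sim: SimulatedDataset,
        foodchain: pd.DataFrame | None = None,
        config: PipelineConfig | None = None,
    ) -> "TracerBudgetModel":
        from .io import validate_dataset

        ds = validate_dataset(
            sim.specimens, sim.batches, sim.incubations, sim.o2_series, foodchain
        )
        return cls(ds, config)

    # ------------------------------------------------------------------
    def _records(self) -> list[flx.IncubationRecord]:
        o2 = self.dataset.o2_series
        by_chamber = {
            cid: list(zip(sub["time_h"], sub["o2_um"]))
            for cid, sub in o2.groupby("chamber_id")
        }
        recs = []
        for _, row in self.dataset.incubations.iterrows():
            r = row.to_dict()
            recs.append(
                flx.IncubationRecord(
                    chamber_id=r["chamber_id"],
                    specimen_id=r["specimen_id"] or None,
                    group=r["group"],
                    chamber_volume=r["chamber_volume_l"],
                    duration=r["duration_h"],
                    dic_start=_opt(r, "dic_start_um"),
                    dic_end=_opt(r, "dic_end_um"),
                    dic_d13c_start=_opt(r, "dic_d13c_start"),
                    dic_d13c_end=_opt(r, "dic_d13c_end"),
                    doc_start=_opt(r, "doc_start_um"),
                    doc_end=_opt(r, "doc_end_um"),
                    poc_start=_opt(r, "poc_start_um"),
                    poc_end=_opt(r, "poc_end_um"),
                    poc_d13c_start=_opt(r, "poc_d13c_start"),
                    poc_d13c_end=_opt(r, "poc_d13c_end"),
                    start_strategy=r.get("start_strategy", "separate_chamber"),
                    refill_volume=r.get("refill_volume_l", 0.0) or 0.0,
                    refill_dic=_opt(r, "refill_dic_um"),
                    refill_doc=_opt(r, "refill_doc_um"),
                    refill_poc=_opt(r, "refill_poc_um"),
                    o2_series=by_chamber.get(r["chamber_id"], []),
                )
            )
        return recs

    def _tissue_oc(self, spec_row: pd.Series) -> float | None:
        oc = _opt(spec_row, "tissue_oc_mol")
        if oc is not None:
            return oc
        vol = _opt(spec_row, "volume_ml")
        if vol is not None and vol > 1:
            return sponge_oc_from_volume(vol, self.config.log_base)
        return None

    def _group_background_fraction(self, recs, group: str, pool: str) -> float | None:
        """Mean start atom fraction over the group's control chambers."""
        cns = self.config.constants
        vals = [
            delta_to_atom_fraction(getattr(r, f"{pool}_d13c_start"), cns)
            for r in recs
            if r.group == group and r.is_control
            and getattr(r, f"{pool}_d13c_start") is not None
        ]
        return float(np.mean(vals)) if vals else None

    # ------------------------------------------------------------------
    def fit(self) -> "TracerBudgetResults":
        cfg = self.config
        cns = cfg.constants
        recs = self._records()
        specimens = self.dataset.specimens.set_index("id", drop=False)
        batches = self.dataset.batches.set_index("id")
        messages = list(self.dataset.validation_report)

        # substrate atom fraction per specimen
        f_sub: dict[str, float] = {}
        for sid, srow in specimens.iterrows():
            bid = srow["substrate_batch_id"]
            if bid:
                f_sub[sid] = float(batches.loc[bid, "atom_fraction"])

        flux_rows = []
        excess_quant = {"dic": "respiration_tracer", "poc": "poc_tracer"}
        for rec in recs:
            per = {"chamber_id": rec.chamber_id, "specimen_id": rec.specimen_id,
                   "group": rec.group, "role": "control" if rec.is_control else "animal"}
            # respiration from the O2 series
            if len(rec.o2_series) >= 3:
                o2_rate, r2 = flx.oxygen_consumption_rate(
                    rec.o2_series, rec.chamber_volume
                )
                flux_rows.append(
                    per | {"quantity": "respiration_total",
                           "raw_rate": flx.respiration_from_oxygen(o2_rate, cns),
                           "r_squared": r2}
                )
            # total POC / DOC release from start/end pairs
            for pool, quantity in _POOL_QUANTITY.items():
                c_end = getattr(rec, f"{pool}_end")
                if getattr(rec, f"{pool}_start") is None or c_end is None:
                    continue
                raw = flx.net_release_rate(
                    rec.effective_start(pool), c_end, rec.chamber_volume, rec.duration
                )
                flux_rows.append(per | {"quantity": quantity, "raw_rate": raw,
                                        "r_squared": np.nan})
            # tracer fluxes, computed in excess-13C space (f_substrate=1)
            for pool, quantity in excess_quant.items():
                if getattr(rec, f"{pool}_d13c_start") is None or \
                        getattr(rec, f"{pool}_d13c_end") is None:
                    continue
                if cfg.background_strategy == "chamber_start":
                    f_bg = None
                else:
                    f_bg = self._group_background_fraction(recs, rec.group, pool)
                excess_rate = flx.tracer_release_rate(rec, pool, f_bg, 1.0, cns)
                flux_rows.append(per | {"quantity": quantity, "raw_rate": excess_rate,
                                        "r_squared": np.nan})
        fluxes = pd.DataFrame(flux_rows)

        # control correction in raw-rate space, per group and quantity
        def corrected(sub: pd.DataFrame) -> pd.DataFrame:
            ctrl = sub.loc[sub["role"] == "control", "raw_rate"]
            out = sub.copy()
            if len(ctrl):
                out["raw_rate_corrected"] = out["raw_rate"] - ctrl.mean()
                out["control_corrected"] = True
            else:
                out["raw_rate_corrected"] = out["raw_rate"]
                out["control_corrected"] = False
            return out

        if len(fluxes) == 0:
            messages.append("no flux-capable chambers found; empty budget")
            empty = pd.DataFrame()
            return TracerBudgetResults(self, empty, fluxes, messages)
        fluxes = (
            fluxes.groupby(["group", "quantity"], group_keys=False)[fluxes.columns]
            .apply(corrected)
            .reset_index(drop=True)
        )
        if not fluxes["control_corrected"].all():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                flx.control_corrected(0.0, [])  # surface the standard warning path
            messages.append("some groups lack controls; their rates are uncorrected")

        # taxon-level unfed background delta13C
        bg = specimens[specimens["is_background"]]
        taxon_background = bg.groupby("taxon")["tissue_delta13c"].mean().to_dict()

        # per-animal standardization, incorporation and budget assembly
        budget_rows = []
        animal_fluxes = fluxes[fluxes["role"] == "animal"]
        for sid, sub in animal_fluxes.groupby("specimen_id"):
            srow = specimens.loc[sid]
            oc = self._tissue_oc(srow)
            if oc is None or oc <= 0:
                messages.append(f"specimen {sid}: no usable tissue OC; skipped")
                continue
            fs = f_sub.get(sid)
            comp: dict[str, flx.FluxResult] = {}
            for _, frow in sub.iterrows():
                raw = frow["raw_rate_corrected"]
                if frow["quantity"] in ("respiration_tracer", "poc_tracer"):
                    if fs is None:
                        continue
                    raw = raw / fs  # excess 13C -> substrate-derived C
                comp[frow["quantity"]] = flx.FluxResult(
                    chamber_id=frow["chamber_id"],
                    specimen_id=sid,
                    quantity=frow["quantity"],
                    raw_rate=raw,
                    rate=flx.standardize_to_biomass(raw, oc),
                    units=flx.STANDARD_RATE_UNITS,
                    control_corrected=bool(frow["control_corrected"]),
                    r_squared=frow.get("r_squared"),
                )
            incorporation = np.nan
            pct_provided = np.nan
            d13c_tissue = _opt(srow, "tissue_delta13c")
            d13c_bg = _opt(srow, "background_delta13c")
            if d13c_bg is None:
                d13c_bg = taxon_background.get(srow["taxon"])
            if d13c_tissue is not None and fs is not None:
                if d13c_bg is None:
                    raise MissingBackgroundError(
                        f"no unfed-conspecific background for taxon {srow['taxon']}"
                    )
                spec = Specimen(
                    id=sid,
                    taxon=srow["taxon"],
                    volume=_opt(srow, "volume_ml"),
                    tissue_oc=oc,
                    tissue_delta13c=d13c_tissue,
                    background_delta13c=d13c_bg,
                    substrate_batch_id=srow["substrate_batch_id"] or None,
                    feeding_hours=_opt(srow, "feeding_hours"),
                )
                incorporation = incorporation_rate(spec, fs, cns)
                bid = srow["substrate_batch_id"]
                provided = (
                    float(batches.loc[bid, "carbon_concentration_um"])
                    * cfg.feeding_volume_l
                )
                incorporated = incorporation * oc * spec.feeding_hours
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    pct_provided = percent_of_provided(incorporated, provided)
                for w in caught:
                    messages.append(f"specimen {sid}: {w.message}")
            required = ("respiration_total", "poc_total",
                        "respiration_tracer", "poc_tracer")
            if not all(q in comp for q in required):
                messages.append(
                    f"specimen {sid}: incomplete fluxes; budget row skipped"
                )
                continue
            row = bud.assemble_budget(
                comp,
                incorporation,
                specimen_id=sid,
                taxon=srow["taxon"],
                group=sub["group"].iloc[0],
            )
            fr = row.tracer_fractions or {}
            budget_rows.append(
                {
                    "specimen_id": sid,
                    "taxon": row.taxon,
                    "group": row.group,
                    "respiration_total": row.respiration_total,
                    "poc_total": row.poc_total,
                    "doc_total": row.doc_total,
                    "total_turnover": row.total_turnover,
                    "incorporation_tracer": row.incorporation_tracer,
                    "respiration_tracer": row.respiration_tracer,
                    "poc_tracer": row.poc_tracer,
                    "frac_incorporation": fr.get("incorporation", np.nan),
                    "frac_respiration": fr.get("respiration", np.nan),
                    "frac_poc": fr.get("poc", np.nan),
                    "tissue_poc_turnover_pct_d": bud.tissue_poc_turnover(row.poc_total),
                    "pct_of_provided": pct_provided,
                }
            )
        budget = pd.DataFrame(budget_rows)
        return TracerBudgetResults(self, budget, fluxes, messages)


@dataclass
class TracerBudgetResults:
    """Fitted per-animal budgets, chamber fluxes and diagnostics."""

    model: TracerBudgetModel
    budget: pd.DataFrame
    fluxes: pd.DataFrame
    messages: list[str] = field(default_factory=list)

    _RATE_COLS = (
        "respiration_total", "poc_total", "doc_total", "total_turnover",
        "incorporation_tracer", "respiration_tracer", "poc_tracer",
    )

    # -- summaries -----------------------------------------------------
    def group_means(self) -> pd.DataFrame:
        """Mean and sd of every standardized rate per condition group."""
        if self.budget.empty:
            return pd.DataFrame()
        return self.budget.groupby("group")[list(self._RATE_COLS)].agg(["mean", "std"])

    def summary(self) -> str:
        cfg = self.model.config
        lines = ["Tracer-flux carbon budget", "=" * 60]
        lines += [f"  {line}" for line in cfg.provenance()]
        lines.append(f"  animals: {len(self.budget)}   groups: "
                     f"{self.budget['group'].nunique() if not self.budget.empty else 0}")
        lines.append("")
        if not self.budget.empty:
            gm = self.budget.groupby("group")[list(self._RATE_COLS)].mean()
            lines.append("Group means [umol C (mol OC)-1 h-1]:")
            lines.append(gm.round(2).to_string())
            lines.append("")
            fr = self.budget.groupby("group")[
                ["frac_incorporation", "frac_respiration", "frac_poc"]
            ].mean()
            lines.append("Mean tracer-C partition (incorporation/respiration/POC):")
            lines.append(fr.round(3).to_string())
        for msg in self.messages:
            lines.append(f"note: {msg}")
        return "\n".join(lines)

    # -- statistics ----------------------------------------------------
    def compare(self, value: str, group: str = "group") -> pd.DataFrame:
        """Kruskal-Wallis + Dunn (or rank-sum) comparison of one rate."""
        cfg = self.model.config
        return nps.compare_groups(
            self.budget, value, group, adjust=cfg.dunn_adjust, alpha=cfg.alpha
        )

    def stats_table(self, values=None, group: str = "group") -> pd.DataFrame:
        values = values or ["incorporation_tracer", "respiration_tracer", "poc_tracer"]
        frames = [self.compare(v, group) for v in values if self.budget[v].notna().any()]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    # -- food chain ----------------------------------------------------
    def food_chain(self):
        if self.model.dataset.foodchain is None:
            raise TracerFluxError("no food-chain table in this dataset")
        return food_chain_record(self.model.dataset.foodchain)

    def transfer_efficiency(self) -> float:
        """Percent of (pseudo-)fecal 13C incorporated by the consumers."""
        return bud.transfer_efficiency(self.food_chain())

    # -- output --------------------------------------------------------
    def to_csv(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        paths = {
            "budget": write_table(self.budget, outdir / "budget.csv", self.model.config),
            "fluxes": write_table(self.fluxes, outdir / "fluxes.csv", self.model.config),
        }
        if not self.budget.empty:
            paths["stats"] = write_table(
                self.stats_table(), outdir / "stats.csv", self.model.config
            )
        return paths

    def plot_budget(self, ax=None):
        """Minimal grouped bar chart of the mean budget components."""
        import matplotlib

        if ax is None:
            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt

            _, ax = plt.subplots(figsize=(7, 4))
        gm = self.budget.groupby("group")[
            ["respiration_total", "poc_total", "doc_total"]
        ].mean()
        gm.plot.bar(ax=ax, rot=30)
        ax.set_ylabel("umol C (mol OC)$^{-1}$ h$^{-1}$")
        ax.set_title("Total-C flux budget (negative = net uptake)")
        ax.figure.tight_layout()
        return ax


def run_pipeline(
    specimens, batches, incubations, o2_series,
    foodchain=None, config: PipelineConfig | None = None, outdir=None,
) -> TracerBudgetResults:
    """Load tables, fit the budget model and optionally write outputs."""
    model = TracerBudgetModel.from_csv(
        specimens, batches, incubations, o2_series, foodchain, config
    )
    results = model.fit()
    if outdir is not None:
        results.to_csv(outdir)
    return results
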