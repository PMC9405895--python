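#!/usr/bin/env python
"""Diagnostic figures for one simulated acquisition (optional; needs matplotlib).

Plots the flow-rate waveform with its 0.15-0.35 Hz band-pass overlay next to
the physio traces, and the detrended-signal PSD with the respiratory and
cardiac integration bands shaded.  PNGs go to scratch/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from rtpcflow.simulate import FlowSimParams, gen_flow_waveform, gen_physio
from rtpcflow.spectral import (
    band_limits,
    bandpass_visual,
    compute_psd,
    detrend_poly,
    find_spectral_peaks,
)

OUT = Path(__file__).resolve().parents[1] / "scratch" / "figures"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    p = FlowSimParams(seed=612)
    flow, _ = gen_flow_waveform(p)
    physio = gen_physio(p)

    fig, axes = plt.subplots(3, 1, figsize=(10, 6), sharex=True)
    axes[0].plot(flow.times, flow.values, lw=0.7, label="flow rate")
    axes[0].plot(flow.times, flow.values.mean() + bandpass_visual(flow), lw=1.5,
                 label="band-pass 0.15-0.35 Hz")
    axes[0].set_ylabel("mL/s")
    axes[0].legend(loc="upper right", fontsize=8)
    t_phys = np.arange(physio.n_samples) / physio.fs
    axes[1].plot(t_phys, physio.resp, lw=0.5)
    axes[1].set_ylabel("belt (a.u.)")
    axes[2].plot(t_phys, physio.pulse, lw=0.5)
    axes[2].set_ylabel("oximeter (a.u.)")
    axes[2].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(OUT / "waveforms.png", dpi=120)

    detrended, _ = detrend_poly(flow)
    spec = compute_psd(detrended, flow.fs)
    hf, vhf = find_spectral_peaks(spec, resp_rate=p.f_r, card_rate=p.f_c)
    bands = band_limits(hf, vhf, nyquist=spec.nyquist)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(spec.freqs, spec.psd, lw=0.8)
    ax.axvspan(bands.resp_lo, bands.resp_hi, alpha=0.2, color="tab:green",
               label="respiratory band")
    ax.axvspan(bands.card_lo, bands.card_hi, alpha=0.2, color="tab:red",
               label="cardiac band")
    ax.set_xlim(0, 4)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("PSD ((mL/s)$^2$/Hz)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(OUT / "psd.png", dpi=120)
    print(f"figures under {OUT}")


if __name__ == "__main__":
    main()
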