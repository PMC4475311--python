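"""Place a strain's CO2-fixation rate among published autotroph rates."""

from hetfix import FixationRecord, load_benchmark, render_comparison, summary_stats

records = load_benchmark()
autos = summary_stats(records, "autotroph")
print(f"{sum(r.group != 'bacteria' for r in records)} autotrophs: "
      f"volumetric {autos.min_rate}-{autos.max_rate} mg CO2/L/h "
      f"(median {autos.median_rate}), specific {autos.min_specific}-{autos.max_specific} mg/g DCW/h")

mine = FixationRecord("my engineered strain", "bacteria", 19.6, 0.87)
print()
print(render_comparison(records, [mine], format="markdown"))
print("A heterotroph at ~20 mg CO2/L/h sits at the autotroph median; its")
print("specific rate (22.5 mg/g DCW/h) is near the top of the autotroph range.")
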