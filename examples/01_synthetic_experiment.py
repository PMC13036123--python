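"""Generate the water x nitrogen factorial experiment.

Builds the default 4 irrigation x 4 nitrogen design (3 replicates, 4
growth stages) and prints its shape plus a reference-evapotranspiration
calculation for one weather day.  The printed ETc is the irrigation
driver: treatment irrigation amounts are fixed fractions of the seasonal
full-irrigation total.
"""

import indicot as ic

cfg = ic.GeneratorConfig(seed=1)
table = ic.generate_experiment(cfg)

print(f"records: {len(table)}  treatments: {table['treatment'].nunique()}")
print(table.groupby("stage_index")[["dm", "lai", "lnc_upper", "lnw_upper"]].mean().round(2))

day = ic.WeatherRecord(rn=13.31, g=0.0, t=16.9, u2=2.078, es=1.997, ea=1.409,
                       delta=0.122, gamma=0.066)
et0 = ic.et0_penman(day)
etc = ic.etc_from_et0(et0, kc=1.15)
print(f"ET0 = {et0:.2f} mm/day, mid-season ETc = {etc:.2f} mm/day")
# ET0 is the FAO-56 reference demand; multiplying by the crop coefficient
# gives the cotton water requirement that the irrigation treatments scale.
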