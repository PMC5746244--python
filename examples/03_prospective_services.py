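"""What-if scenario: candidate services the clinic could add.

Prices a prospective menu — 10 colonoscopy referrals, universal depression
screening (500 patients) and 50 cholesterol screenings per year — to rank
additions by expected QALYs/year before committing budget to them.
"""

from cpbsim import builtin_menu_path, load_rate_table, read_service_menu, scenario_impact
from cpbsim.reporting import render_impact_table

rates = load_rate_table()
menu = read_service_menu(builtin_menu_path("ucc_prospective"), rates)
table = scenario_impact(menu)

print(render_impact_table(table))
best = max(table.rows, key=lambda r: r.qalys_mean)
print(
    f"Highest-impact addition: {best.intervention} "
    f"({best.qalys_mean:.2f} QALYs/year, ${best.kdollars_mean:,.0f}k/year)."
)
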