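"""Descriptive survey summaries: who reports how many contacts, of what kind.

Produces the stratified tables a contact survey normally reports: contact
counts by group-size band / setting / touch / frequency / duration with
column percentages per participant age group, and median daily contact
counts per stratum.
"""

from contact_triad import SyntheticConfig, descriptive_report, generate_survey

tables, _ = generate_survey(
    SyntheticConfig(n_locations=8, households_per_location=8, seed=2))
report = descriptive_report(tables)

cc = report["contact_characteristics"]
total = cc[cc["age_group"] == "total"]
print("contacts by setting (column % of all reported contacts):")
for _, row in total[total["characteristic"] == "setting"].iterrows():
    print(f"  {row['level']:8s} {row['contacts']:7d}  ({row['percent']:.0f}%)")

print("\ncontacts by group-size band:")
for _, row in total[total["characteristic"] == "group_size_band"].iterrows():
    print(f"  {row['level']:8s} {row['contacts']:7d}  ({row['percent']:.0f}%)")

daily = report["daily_contacts"]
age = daily[daily["stratum"] == "age_group"]
print("\ndaily reported contacts by participant age group:")
for _, row in age.iterrows():
    print(f"  {row['level']:8s} median {row['median']:5.1f}  "
          f"IQR [{row['q25']:.0f}, {row['q75']:.0f}]  mean {row['mean']:5.1f}")
print("\nPercentages are column percentages within each table block; group "
      "contacts contribute their full group size to the contact counts.")
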