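# Provider unit spellings mapped to canonical unit symbols.
# Keys are canonical symbols; values list the spellings seen in source strings.
# Extend at run time with specieskg.units.register_alias(spelling, canonical).

[aliases]
"K" = ["K", "kelvin", "Kelvin", "deg K", "°K"]
"°C" = ["°C", "C", "deg C", "degC", "ºC", "deg. C"]
"°F" = ["°F", "F", "deg F", "degF", "ºF", "deg. F"]
"kPa" = ["kPa"]
"Pa" = ["Pa"]
"hPa" = ["hPa"]
"mmHg" = ["mmHg", "mm Hg", "torr", "Torr"]
"atm" = ["atm", "atmosphere", "atmospheres"]
"bar" = ["bar"]
"mg/L" = ["mg/L", "mg/l", "mg/liter"]
"g/L" = ["g/L", "g/l"]
"mg/mL" = ["mg/mL", "mg/ml"]
"g/mL" = ["g/mL", "g/ml"]
"kg/m³" = ["kg/m³", "kg/m3", "kg/cu m", "kg m-3"]
"g/cm³" = ["g/cm³", "g/cm3", "g/cu cm", "g cm-3"]
"g/mol" = ["g/mol", "g mol-1"]
"kg/mol" = ["kg/mol"]
"Da" = ["Da", "dalton", "daltons", "amu", "u"]
"e" = ["e"]
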