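# Curated unit-variable lexicon.
# Sections: [units] canonical / surfaces (|-separated) / dimension / variables (|-separated, first = default)
#           [variables] name / trigger_words (|-separated)
#           [combinations] pattern of dimensions (|-separated) / joiners / variable
# Surface matching is exact-case first, then case-insensitive where unambiguous
# (so "mM" = millimolar never collides with "mm" = millimeter).
[units]
canonical	surfaces	dimension	variables
meter	meter|meters|metre|metres|m|mt|mts	linear	size|depth|length|distance|height|width|diameter
centimeter	centimeter|centimeters|centimetre|centimetres|cm	linear	size|depth|length|distance|height|width|diameter
millimeter	millimeter|millimeters|millimetre|millimetres|mm	linear	size|depth|length|distance|height|width|diameter
micrometer	micrometer|micrometers|micrometre|um|µm|micron|microns	linear	size|length|diameter|width
nanometer	nanometer|nanometers|nanometre|nm	linear	size|length|diameter
kilometer	kilometer|kilometers|kilometre|kilometres|km|kms	linear	distance|depth|length|size
decimeter	decimeter|decimeters|dm	linear	size|depth|length
angstrom	angstrom|angstroms	linear	size|length|diameter
inch	inch|inches	linear	size|length|width|diameter
foot	foot|feet|ft	linear	size|depth|length|height
yard	yard|yards|yd	linear	size|length|distance
mile	mile|miles|mi	linear	distance|size|length
nautical mile	nautical mile|nautical miles	linear	distance
fathom	fathom|fathoms	linear	depth
gram	gram|grams|gr|grs|g	mass	weight
kilogram	kilogram|kilograms|kg|kgs|kilo|kilos	mass	weight
milligram	milligram|milligrams|mg|mgs	mass	weight
microgram	microgram|micrograms|ug|µg	mass	weight
nanogram	nanogram|nanograms|ng	mass	weight
picogram	picogram|picograms|pg	mass	weight
femtogram	femtogram|femtograms|fg	mass	weight
ton	ton|tons|tonne|tonnes	mass	weight
pound	pound|pounds|lb|lbs	mass	weight
liter	liter|liters|litre|litres|l|L	volume	volume
milliliter	milliliter|milliliters|millilitre|millilitres|ml|mls	volume	volume
microliter	microliter|microliters|microlitre|ul|µl	volume	volume
nanoliter	nanoliter|nanoliters|nl	volume	volume
picoliter	picoliter|picoliters|pl	volume	volume
deciliter	deciliter|deciliters|dl	volume	volume
cubic meter	cubic meter|cubic meters|m3	volume	volume
cubic centimeter	cubic centimeter|cubic centimeters|cm3|cc	volume	volume
gallon	gallon|gallons|gal	volume	volume
second	second|seconds|sec|secs|s	time	time
minute	minute|minutes|min|mins	time	time
hour	hour|hours|hr|hrs|h	time	time
day	day|days|d	time	time
week	week|weeks|wk|wks	time	time
month	month|months|mo	time	time
year	year|years|yr|yrs	time	time
millisecond	millisecond|milliseconds|ms	time	time
decade	decade|decades	time	time
generation	generation|generations	time	time
degree c	degree c|degrees c|°c|deg c|celsius|c	temperature	temperature
degree f	degree f|degrees f|°f|fahrenheit	temperature	temperature
kelvin	kelvin|K	temperature	temperature
mole	mole|moles|mol	amount	concentration
millimole	millimole|millimoles|mmol	amount	concentration
micromole	micromole|micromoles|umol|µmol	amount	concentration
nanomole	nanomole|nanomoles|nmol	amount	concentration
picomole	picomole|picomoles|pmol	amount	concentration
molar	molar|M	amount	concentration
millimolar	millimolar|mM	amount	concentration
micromolar	micromolar|uM|µM	amount	concentration
nanomolar	nanomolar|nM	amount	concentration
picomolar	picomolar|pM	amount	concentration
osmol	osmol|mosmol	amount	concentration
equivalent	equivalent|equivalents|meq	amount	concentration
cell	cell|cells	count	cell number
colony forming unit	colony forming unit|cfu	count	cell number
spore	spore|spores	count	cell number
individual	individual|individuals	count	cell number
copy	copy|copies	count	copy number
pascal	pascal|pascals|pa	pressure_base	pressure
kilopascal	kilopascal|kilopascals|kpa|kPa	pressure_base	pressure
megapascal	megapascal|megapascals|mpa|MPa	pressure_base	pressure
bar	bar|bars	pressure_base	pressure
millibar	millibar|millibars|mbar	pressure_base	pressure
atmosphere	atmosphere|atmospheres|atm	pressure_base	pressure
psi	psi	pressure_base	pressure
torr	torr	pressure_base	pressure
mm hg	mm hg|mmhg	pressure_base	pressure
square meter	square meter|square meters|square metre|m2|sq m	area	area
square centimeter	square centimeter|square centimeters|cm2	area	area
square millimeter	square millimeter|square millimeters|mm2	area	area
square kilometer	square kilometer|square kilometers|km2	area	area
hectare	hectare|hectares|ha	area	area
acre	acre|acres	area	area
ph	ph|pH	other	ph
psu	psu	other	salinity
ppt	ppt	other	salinity|concentration
ppm	ppm	other	concentration
ppb	ppb	other	concentration
percent	percent|percentage|%	other	concentration
rpm	rpm	other	speed
knot	knot|knots	other	speed
volt	volt|volts|V	other	voltage
millivolt	millivolt|millivolts|mV	other	voltage
watt	watt|watts|W	other	power
joule	joule|joules|J	other	energy
kilojoule	kilojoule|kilojoules|kj|kJ	other	energy
calorie	calorie|calories|cal	other	energy
kilocalorie	kilocalorie|kilocalories|kcal	other	energy
microeinstein	microeinstein|microeinsteins|uE	other	light intensity
lux	lux	other	light intensity
hertz	hertz|hz|Hz	other	frequency
curie	curie|curies|Ci	other	radioactivity
becquerel	becquerel|becquerels|bq	other	radioactivity
gray	gray|gy|Gy	other	radioactivity
roentgen	roentgen	other	radioactivity
dalton	dalton|daltons|da	other	molecular weight
kilodalton	kilodalton|kilodaltons|kda|kDa	other	molecular weight
siemens	siemens	other	conductivity
millisiemens	millisiemens|mS	other	conductivity
microsiemens	microsiemens|uS|µS	other	conductivity
ampere	ampere|amperes|amp|amps	other	current
milliampere	milliampere|milliamperes|mA	other	current
degree	degree|degrees	angle	angle
base pair	base pair|base pairs|bp	other	length
kilobase	kilobase|kilobases|kb	other	length
nucleotide	nucleotide|nucleotides|nt	other	length
[variables]
name	trigger_words
temperature	temperature|temperatures|temp
size	size|sizes
volume	volume|volumes|vol
ph	ph
concentration	concentration|concentrations|concentrated
time	time|duration|period
weight	weight|weighed|mass
area	area|areas
pressure	pressure|pressures
salinity	salinity|saline
depth	depth|depths|deep
length	length|lengths|long
distance	distance|distances|away
height	height|heights|tall
width	width|widths|wide
diameter	diameter|diameters|diam
speed	speed|velocity|spun
flux	flux|flow
cell number	cell number|cells|abundance
cell density	cell density|density
radioactivity	radioactivity|radioactive|activity
voltage	voltage|potential
conductivity	conductivity|conductance
rate of temperature change	rate of temperature change|ramp|heating|cooling
rate of concentration change	rate of concentration change|rate
diffusion coefficient	diffusion coefficient|diffusion|diffusivity
enzymatic specific activity	enzymatic specific activity|specific|enzymatic
angle	angle|inclination|slope
molecular weight	molecular weight|molecular
density	density|dense
humidity	humidity|humid|moisture
light intensity	light intensity|light|irradiance|illumination
areal concentration	areal concentration|application|applied|loading
frequency	frequency|frequencies
current	current|amperage
copy number	copy number|copies|copy
power	power
energy	energy
[combinations]
pattern	joiners	variable
mass|volume	/|per|-1	concentration
amount|volume	/|per|-1	concentration
mass|mass	/|per|-1	concentration
volume|volume	/|per|-1	concentration
mass|area	/|per|-1	areal concentration
count|area	/|per|-1	cell density
count|volume	/|per|-1	cell density
volume|time	/|per|-1	flux
mass|time	/|per|-1	flux
linear|time	/|per|-1	speed
temperature|time	/|per|-1	rate of temperature change
amount|volume|time	/|per|-1	rate of concentration change
mass|volume|time	/|per|-1	rate of concentration change
area|time	/|per|-1	diffusion coefficient
amount|time|mass	/|per|-1	enzymatic specific activity
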