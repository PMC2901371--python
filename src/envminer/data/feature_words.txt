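# Generic geographic feature terms (English, Spanish, French, Portuguese,
# Arabic transliterations). A capitalized phrase absent from the gazetteer but
# containing one of these words is accepted as a location without coordinates.
archipelago
atoll
bahia
baie
basin
bay
beach
bluff
bog
brook
cabo
canal
canyon
cape
cascade
cave
cay
channel
cliff
coast
cordillera
cove
crater
creek
delta
desert
dune
dunes
estuary
falls
fen
fjord
fjords
floodplain
foret
forest
geyser
glacier
gorge
grotto
gulf
harbor
harbour
headland
highland
highlands
hill
hills
hot springs
ile
ilha
inlet
isla
island
islands
isle
islet
jabal
jebel
jungle
knoll
lac
lago
lagoa
lagoon
laguna
lake
loch
marsh
massif
meadow
mesa
mont
montana
monte
moor
mount
mountain
mountains
mouth
oasis
ocean
pass
peak
peaks
peninsula
plain
plains
plateau
playa
point
pond
pool
port
prairie
praia
quebrada
rapids
ras
reef
ria
ridge
rio
river
riviere
rock
rocks
sands
savanna
sea
seamount
serra
shoal
shore
sierra
sound
spring
springs
steppe
strait
strand
stream
summit
swamp
trench
tundra
vale
valle
vallee
valley
volcan
volcano
wadi
waterfall
wetland
wood
woods
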