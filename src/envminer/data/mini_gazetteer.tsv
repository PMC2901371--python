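name	alternate_names	latitude	longitude	country_code	admin_parent	feature_class	relevance_rank
Australia		-25.2744	133.7751	AU		PCLI	1
Brazil		-10.3333	-53.2	BR		PCLI	1
Canada		56.1304	-106.3468	CA		PCLI	1
Chile		-31.7613	-71.3188	CL		PCLI	1
China		35.0	105.0	CN		PCLI	1
Costa Rica		9.7489	-83.7534	CR		PCLI	1
Egypt		26.8206	30.8025	EG		PCLI	1
France		46.2276	2.2137	FR		PCLI	1
Germany		51.1657	10.4515	DE		PCLI	1
Iceland		64.9631	-19.0208	IS		PCLI	1
India		20.5937	78.9629	IN		PCLI	1
Italy		41.8719	12.5674	IT		PCLI	1
Jamaica		18.1096	-77.2975	JM		PCLI	1
Japan		36.2048	138.2529	JP		PCLI	1
Kenya		-0.0236	37.9062	KE		PCLI	1
Mexico		23.6345	-102.5528	MX		PCLI	1
Morocco		31.7917	-7.0926	MA		PCLI	1
Norway		60.472	8.4689	NO		PCLI	1
Peru		-9.19	-75.0152	PE		PCLI	1
Russia		61.524	105.3188	RU		PCLI	1
South Africa		-30.5595	22.9375	ZA		PCLI	1
South Korea	Korea	35.9078	127.7669	KR		PCLI	1
Spain		40.4637	-3.7492	ES		PCLI	1
Switzerland		46.8182	8.2275	CH		PCLI	1
United Kingdom	England|Great Britain|UK	55.3781	-3.436	GB		PCLI	1
United States	United States of America|USA	37.0902	-95.7129	US		PCLI	1
Venezuela		6.4238	-66.5897	VE		PCLI	1
Margate		-30.8636	30.3706	ZA	South Africa	PPL	1
Margate		51.3813	1.3862	GB	England	PPL	2
Margate		-43.0279	147.2623	AU	Tasmania	PPL	3
Margate		26.2445	-80.2064	US	United States	PPL	4
Margate		46.405	-63.5	CA	Canada	PPL	5
Tasmania		-42.0	147.0	AU	Australia	ADM1	1
San Jose	San José	9.9281	-84.0907	CR	Costa Rica	PPL	1
San Jose	San José	37.3382	-121.8863	US	United States	PPL	2
San Jose	San José de Guanipa	8.8925	-64.1611	VE	Venezuela	PPL	3
Richmond		37.5407	-77.436	US	United States	PPL	1
Richmond		51.4613	-0.3037	GB	England	PPL	2
Richmond		49.1666	-123.1336	CA	Canada	PPL	3
Richmond		-33.5994	150.7491	AU	Australia	PPL	4
Springfield		39.8017	-89.6437	US	United States	PPL	1
Springfield		42.1015	-72.5898	US	United States	PPL	2
Kingston		17.9971	-76.7936	JM	Jamaica	PPL	1
Caracas		10.4806	-66.9036	VE	Venezuela	PPL	1
Lake Cadagno		46.55	8.7117	CH	Switzerland	LK	1
Piora Valley	Val Piora	46.5486	8.73	CH	Switzerland	VAL	1
Boston		42.3601	-71.0589	US	United States	PPL	1
Hobart		-42.8826	147.3257	AU	Tasmania	PPL	1
Launceston		-41.4388	147.1347	AU	Tasmania	PPL	1
Gulf of Mexico		25.0	-90.0	MX	Mexico	GULF	1
Mid-Atlantic Ridge		0.0	-25.0			RDGU	1
Mariana Trench		11.35	142.2			TRNU	1
Nairobi		-1.2921	36.8219	KE	Kenya	PPL	1
Mombasa		-4.0435	39.6682	KE	Kenya	PPL	1
Barcelona		41.3851	2.1734	ES	Spain	PPL	1
Valencia		39.4699	-0.3763	ES	Spain	PPL	1
Zurich	Zürich	47.3769	8.5417	CH	Switzerland	PPL	1
Geneva		46.2044	6.1432	CH	Switzerland	PPL	1
Bern		46.948	7.4474	CH	Switzerland	PPL	1
Lyon		45.764	4.8357	FR	France	PPL	1
Marseille		43.2965	5.3698	FR	France	PPL	1
Toulouse		43.6047	1.4442	FR	France	PPL	1
Hamburg		53.5511	9.9937	DE	Germany	PPL	1
Munich	München	48.1351	11.582	DE	Germany	PPL	1
Heidelberg		49.3988	8.6724	DE	Germany	PPL	1
Kyoto		35.0116	135.7681	JP	Japan	PPL	1
Osaka		34.6937	135.5023	JP	Japan	PPL	1
Sapporo		43.0618	141.3545	JP	Japan	PPL	1
Cusco	Cuzco	-13.5319	-71.9675	PE	Peru	PPL	1
Arequipa		-16.409	-71.5375	PE	Peru	PPL	1
Valparaiso	Valparaíso	-33.0472	-71.6127	CL	Chile	PPL	1
Antofagasta		-23.6509	-70.3975	CL	Chile	PPL	1
Alexandria		31.2001	29.9187	EG	Egypt	PPL	1
Casablanca		33.5731	-7.5898	MA	Morocco	PPL	1
Busan		35.1796	129.0756	KR	South Korea	PPL	1
Daejeon		36.3504	127.3845	KR	South Korea	PPL	1
Salvador		-12.9777	-38.5016	BR	Brazil	PPL	1
Manaus		-3.119	-60.0217	BR	Brazil	PPL	1
Recife		-8.0476	-34.877	BR	Brazil	PPL	1
Oaxaca		17.0732	-96.7266	MX	Mexico	PPL	1
Merida	Mérida	20.9674	-89.5926	MX	Mexico	PPL	1
Pune		18.5204	73.8567	IN	India	PPL	1
Jaipur		26.9124	75.7873	IN	India	PPL	1
Varanasi		25.3176	82.9739	IN	India	PPL	1
Guangzhou		23.1291	113.2644	CN	China	PPL	1
Chengdu		30.5728	104.0668	CN	China	PPL	1
Qingdao		36.0671	120.3826	CN	China	PPL	1
Perth		-31.9505	115.8605	AU	Australia	PPL	1
Durban		-29.8587	31.0218	ZA	South Africa	PPL	1
Pretoria		-25.7479	28.2293	ZA	South Africa	PPL	1
Cardiff		51.4816	-3.1791	GB	England	PPL	1
Leeds		53.8008	-1.5491	GB	England	PPL	1
Calgary		51.0447	-114.0719	CA	Canada	PPL	1
Halifax		44.6488	-63.5752	CA	Canada	PPL	1
Monteverde		10.3	-84.8167	CR	Costa Rica	PPL	1
Maracaibo		10.6666	-71.6124	VE	Venezuela	PPL	1
Tromso	Tromsø	69.6492	18.9553	NO	Norway	PPL	1
Bergen		60.3913	5.3221	NO	Norway	PPL	1
Reykjavik	Reykjavík	64.1466	-21.9426	IS	Iceland	PPL	1
Akureyri		65.6826	-18.0907	IS	Iceland	PPL	1
Turin	Torino	45.0703	7.6869	IT	Italy	PPL	1
Naples	Napoli	40.8518	14.2681	IT	Italy	PPL	1
Lake Victoria		-1.0	33.0	KE	Kenya	LK	1
Lake Baikal		53.5	108.0	RU	Russia	LK	1
Lake Geneva	Lac Léman	46.45	6.55	CH	Switzerland	LK	1
Lake Titicaca		-15.8402	-69.3354	PE	Peru	LK	1
Amazon River	Rio Amazonas	-2.0	-55.0	BR	Brazil	STM	1
Mount Fuji	Fujisan	35.3606	138.7274	JP	Japan	MT	1
Atacama Desert		-24.5	-69.25	CL	Chile	DSRT	1
Great Barrier Reef		-18.2871	147.6992	AU	Australia	RF	1
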